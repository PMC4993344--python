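"""End-to-end pipeline: clock -> association -> ewas -> network -> enrichment.

Each stage reads the shared in-memory state, writes its TSV outputs into the
run directory, and records warnings/timings in the run manifest.  Stage
failures abort the run with a stage-labelled error.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from comethage import __version__
from comethage.association import ModelSpec, coefficient_to_years, fit_model, kruskal_wallis, principal_components
from comethage.clock import (
    age_acceleration,
    dnam_age,
    fit_control_trend,
    intrinsic_acceleration,
    read_clock,
    winsorize_dnam_age,
)
from comethage.core_io import (
    BetaMatrix,
    SampleSheet,
    ValidationError,
    align,
    read_annotation,
    read_beta_matrix,
    read_sample_sheet,
)
from comethage.enrichment import (
    enrichment_table,
    gene_cpg_groups,
    gene_module_assignment,
    read_gmt,
    select_representatives,
)
from comethage.ewas import (
    EwasConfig,
    adjust_age_sex,
    bonferroni_threshold,
    ewas_per_lobe,
    inflation_lambda,
    manhattan_export,
    meta_analyse,
    variance_filter,
)
from comethage.network import (
    NetworkConfig,
    calibrate_toms,
    consensus_dissimilarity,
    cut_modules,
    membership_table,
    module_eigenvector,
    module_trait_meta,
    signed_hybrid_adjacency,
    tom,
)

log = logging.getLogger(__name__)

ALL_STAGES = ["clock", "association", "ewas", "network", "enrichment"]


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    beta_paths: dict           # lobe -> path
    sheet_path: str
    clock_path: str
    annotation_path: str = ""
    gene_sets_path: str = ""
    out_dir: str = "run"
    stages: list = field(default_factory=lambda: list(ALL_STAGES))
    seed: int = 0
    winsorize_threshold: float = 15.0
    ewas: EwasConfig = field(default_factory=EwasConfig)
    network: NetworkConfig = field(default_factory=NetworkConfig)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        ewas_cfg = EwasConfig(**raw.pop("ewas", {}))
        net_cfg = NetworkConfig(**raw.pop("network", {}))
        return cls(ewas=ewas_cfg, network=net_cfg, **raw)

    def validate(self):
        missing = [p for p in [*self.beta_paths.values(), self.sheet_path, self.clock_path]
                   if not Path(p).exists()]
        for p in (self.annotation_path, self.gene_sets_path):
            if p and not Path(p).exists():
                missing.append(p)
        if missing:
            raise ValidationError(f"missing input files: {missing}")
        bad = [s for s in self.stages if s not in ALL_STAGES]
        if bad:
            raise ValidationError(f"unknown stages: {bad}")
        if "enrichment" in self.stages and "network" not in self.stages:
            raise ValidationError(
                "enrichment requires the network stage (module labels); "
                "enable 'network' or drop 'enrichment'"
            )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


class Pipeline:
    def __init__(self, config: RunConfig):
        config.validate()
        self.config = config
        self.out = Path(config.out_dir)
        self.out.mkdir(parents=True, exist_ok=True)
        self.manifest = {
            "version": __version__,
            "seed": config.seed,
            "stages": {},
            "warnings": [],
            "outputs": {},
        }
        self.state: dict = {}

    # ---- data loading ----------------------------------------------------

    def load_inputs(self):
        cfg = self.config
        sheet = read_sample_sheet(cfg.sheet_path)
        betas = {}
        for lobe, path in cfg.beta_paths.items():
            bm = read_beta_matrix(path)
            bm, _, dropped_b, _ = align(bm, sheet)
            if dropped_b:
                log.warning("lobe %s: dropped %d samples absent from sheet", lobe, len(dropped_b))
            betas[lobe] = bm
        self.state["sheet"] = sheet
        self.state["betas"] = betas
        self.state["clock_model"] = read_clock(cfg.clock_path)
        if cfg.annotation_path:
            self.state["annotation"] = read_annotation(cfg.annotation_path)
        if cfg.gene_sets_path:
            self.state["gene_sets"] = read_gmt(cfg.gene_sets_path)

    # ---- stages ----------------------------------------------------------

    def stage_clock(self):
        cfg = self.config
        sheet: SampleSheet = self.state["sheet"]
        betas = self.state["betas"]
        model = self.state["clock_model"]
        frames = [dnam_age(bm, model) for bm in betas.values()]
        dn = pd.concat(frames)
        info = sheet.table.loc[dn.index]
        records = pd.DataFrame(
            {
                "sample_id": dn.index,
                "individual_id": info["individual_id"].to_numpy(),
                "region": info["region"].to_numpy(),
                "lobe": info["lobe"].to_numpy(),
                "diagnosis": info["diagnosis"].to_numpy(),
                "age": info["age"].to_numpy(dtype=float),
                "sex": info["sex"].to_numpy(),
                "bank": info["bank"].to_numpy(),
                "prop_neurons": info["prop_neurons"].to_numpy(dtype=float),
                "dnam_age": dn.to_numpy(),
            }
        )
        controls = records["diagnosis"] != "HD"
        trend = fit_control_trend(records.loc[controls, "age"], records.loc[controls, "dnam_age"])
        records = winsorize_dnam_age(records, trend, threshold=cfg.winsorize_threshold)
        # refit once on winsorized estimates
        trend = fit_control_trend(records.loc[controls, "age"], records.loc[controls, "dnam_age"])
        records["age_accel"] = age_acceleration(records["dnam_age"], records["age"], trend)
        if records["prop_neurons"].notna().all():
            records["intrinsic_accel"] = intrinsic_acceleration(
                records["dnam_age"], records["age"], records["prop_neurons"]
            )
        else:
            records["intrinsic_accel"] = np.nan
            self.manifest["warnings"].append("prop_neurons missing; intrinsic acceleration skipped")
        h, p = kruskal_wallis(records["age_accel"].to_numpy(), records["diagnosis"].to_numpy())
        summary = {
            "kruskal_wallis_accel": {"H": h, "p": p},
            "mean_accel": {
                d: float(records.loc[records["diagnosis"] == d, "age_accel"].mean())
                for d in records["diagnosis"].unique()
            },
            "n_winsorized": int(records["winsorized"].sum()),
            "corr_dnam_age": float(np.corrcoef(records["dnam_age"], records["age"])[0, 1]),
        }
        self.state["accel_records"] = records
        self.state["trend"] = trend
        self._write_tsv(records, "acceleration.tsv")
        self.manifest["stages"]["clock"] = summary

    def stage_association(self):
        records = self.state["accel_records"].copy()
        betas = self.state["betas"]
        # PCs on concatenated lobes, restricted to the acceleration samples
        joint = pd.concat([bm.to_frame() for bm in betas.values()], axis=1)
        joint = joint.loc[:, records["sample_id"]]
        pcs = principal_components(joint.to_numpy(), 5)
        for j in range(5):
            records[f"PC{j + 1}"] = pcs[:, j]
        records["huntington"] = (records["diagnosis"] == "HD").astype(float)
        # frontal reference, matched to whatever region label maps to that lobe
        frontal = records.loc[records["lobe"] == "frontal", "region"]
        refs = {"diagnosis": "control", "sex": "M", "bank": "NewZealand",
                "region": frontal.iloc[0] if len(frontal) else "frontal"}
        specs = {
            "model1": ModelSpec(["huntington", "age", "sex", "bank", "region"], refs),
            "model2": ModelSpec(["huntington", "age", "sex", "bank", "region", "prop_neurons"], refs),
            "model3": ModelSpec(["huntington", "age", "sex", "bank", "region",
                                 "PC1", "PC2", "PC3", "PC4", "PC5"], refs),
        }
        tables = []
        summary = {}
        for name, spec in specs.items():
            if name == "model2" and records["prop_neurons"].isna().any():
                self.manifest["warnings"].append("prop_neurons missing; model 2 skipped")
                continue
            fit = fit_model(records, spec)
            t = fit.table.copy()
            t.insert(0, "model", name)
            tables.append(t)
            hd = fit.coef("huntington")
            age = fit.coef("age")
            summary[name] = {
                "hd_coef": hd,
                "age_coef": age,
                "years": coefficient_to_years(hd, age),
                "hd_p": float(t.set_index("term").at["huntington", "p"]),
            }
        self._write_tsv(pd.concat(tables, ignore_index=True), "models.tsv")
        self.manifest["stages"]["association"] = summary

    def stage_ewas(self):
        cfg = self.config
        sheet: SampleSheet = self.state["sheet"]
        betas = self.state["betas"]
        kept, report = variance_filter(betas, cfg.ewas.variance_threshold)
        residuals = {}
        per_lobe = {}
        for lobe, bm in betas.items():
            sub = bm.subset_cpgs(kept)
            res = adjust_age_sex(sub, sheet)
            residuals[lobe] = res
            diag = sheet.table.loc[res.columns, "diagnosis"].to_numpy()
            per_lobe[lobe] = ewas_per_lobe(res, diag, min_group_size=cfg.ewas.min_group_size)
        meta = meta_analyse(per_lobe)
        lam = {lobe: inflation_lambda(t["p"].to_numpy()) for lobe, t in per_lobe.items()}
        lam["meta"] = inflation_lambda(meta["p_meta"].to_numpy())
        threshold = bonferroni_threshold(cfg.ewas.alpha, cfg.ewas.bonferroni_denominator)
        n_hits = int((meta["p_meta"] < threshold).sum())
        self.state["residuals"] = residuals
        self.state["ewas_meta"] = meta
        for lobe, t in per_lobe.items():
            self._write_tsv(t.reset_index(names="cpg_id"), f"ewas_{lobe}.tsv")
        self._write_tsv(meta.reset_index(names="cpg_id"), "ewas_meta.tsv")
        if "annotation" in self.state:
            mh = manhattan_export(
                meta,
                self.state["annotation"],
                alpha=cfg.ewas.alpha,
                bonferroni_denominator=cfg.ewas.bonferroni_denominator,
                figure_path=self.out / "manhattan.png",
            )
            self._write_tsv(mh, "manhattan.tsv")
        self.manifest["stages"]["ewas"] = {
            "variance_filter": report,
            "lambda": lam,
            "bonferroni_threshold": threshold,
            "significant_cpgs": n_hits,
            "note": "meta p-values are descriptive, not inferential",
        }

    def stage_network(self):
        cfg = self.config
        sheet: SampleSheet = self.state["sheet"]
        if "residuals" not in self.state:
            # network can run without the ewas stage; redo filter+adjust
            kept, _ = variance_filter(self.state["betas"], cfg.ewas.variance_threshold)
            self.state["residuals"] = {
                lobe: adjust_age_sex(bm.subset_cpgs(kept), sheet)
                for lobe, bm in self.state["betas"].items()
            }
        residuals = self.state["residuals"]
        adjacency = {}
        toms = {}
        for lobe, res in residuals.items():
            A = signed_hybrid_adjacency(res, cfg.network)
            adjacency[lobe] = A
            toms[lobe] = tom(A)
        ctoms = calibrate_toms(toms)
        cons_diss = consensus_dissimilarity(ctoms, cfg.network.consensus_quantile)
        cpg_ids = list(next(iter(residuals.values())).index)
        modules = cut_modules(cons_diss, cpg_ids, cfg.network)
        eig = {lobe: {} for lobe in residuals}
        varex = []
        for lobe, res in residuals.items():
            for m in modules.module_ids:
                e, ve = module_eigenvector(res, modules.members(m))
                eig[lobe][m] = e
                varex.append({"lobe": lobe, "module": m, "variance_explained": ve})
        traits = {
            lobe: (sheet.table.loc[res.columns, "diagnosis"] == "HD").to_numpy(dtype=float)
            for lobe, res in residuals.items()
        }
        trait_meta = (
            module_trait_meta(eig, traits, cfg.network.max_p_outliers)
            if modules.module_ids
            else pd.DataFrame()
        )
        mm = membership_table(residuals, eig) if modules.module_ids else pd.DataFrame()
        self.state["adjacency"] = adjacency
        self.state["modules"] = modules
        self.state["eigenvectors"] = eig
        self._write_tsv(modules.to_frame(), "modules.tsv")
        if modules.module_ids:
            for lobe in eig:
                df = pd.DataFrame({f"module_{m}": eig[lobe][m] for m in modules.module_ids})
                self._write_tsv(df.reset_index(names="sample_id"), f"eigenvectors_{lobe}.tsv")
            self._write_tsv(pd.DataFrame(varex), "variance_explained.tsv")
            self._write_tsv(mm, "module_membership.tsv")
            self._write_tsv(trait_meta, "module_trait.tsv")
        n_mod = len(modules.module_ids)
        module_threshold = bonferroni_threshold(0.05, max(n_mod, 1))
        sig = (
            trait_meta[trait_meta["p_meta"] < module_threshold]["module"].tolist()
            if n_mod
            else []
        )
        self.manifest["stages"]["network"] = {
            "n_modules": n_mod,
            "consensus_quantile": cfg.network.consensus_quantile,
            "cut_height": modules.cut_height,
            "module_threshold": module_threshold,
            "significant_modules": sig,
        }

    def stage_enrichment(self):
        cfg = self.config
        if "annotation" not in self.state or "gene_sets" not in self.state:
            raise ValidationError("enrichment needs annotation_path and gene_sets_path")
        modules = self.state["modules"]
        residuals = self.state["residuals"]
        adjacency = self.state["adjacency"]
        cpg_ids = modules.cpg_ids
        groups = gene_cpg_groups(self.state["annotation"], cpg_ids)
        cpg_index = {c: i for i, c in enumerate(cpg_ids)}
        reps = select_representatives(
            groups, adjacency, cpg_index, residuals, cfg.network.consensus_quantile
        )
        labels = dict(zip(modules.cpg_ids, modules.labels))
        assignments = gene_module_assignment(reps, labels)
        enr = enrichment_table(assignments, self.state["gene_sets"])
        self._write_tsv(assignments, "gene_representatives.tsv")
        self._write_tsv(enr, "enrichment.tsv")
        self.manifest["stages"]["enrichment"] = {
            "n_genes": int(len(assignments)),
            "rules": assignments["rule"].value_counts().to_dict(),
            "top_p": float(enr["p"].min()) if len(enr) else None,
        }

    # ---- driver ----------------------------------------------------------

    def _write_tsv(self, df: pd.DataFrame, name: str):
        path = self.out / name
        df.to_csv(path, sep="\t", index=False, float_format="%.8g")
        self.manifest["outputs"][name] = None  # checksum filled at the end

    def run(self) -> dict:
        self.load_inputs()
        stage_fns = {
            "clock": self.stage_clock,
            "association": self.stage_association,
            "ewas": self.stage_ewas,
            "network": self.stage_network,
            "enrichment": self.stage_enrichment,
        }
        order = [s for s in ALL_STAGES if s in self.config.stages]
        if "association" in order and "clock" not in order:
            raise ValidationError("association requires the clock stage")
        for stage in order:
            t0 = time.time()
            log.info("running stage %s", stage)
            try:
                with warnings.catch_warnings(record=True) as caught:
                    warnings.simplefilter("always")
                    stage_fns[stage]()
                for w in caught:
                    self.manifest["warnings"].append(f"{stage}: {w.message}")
            except Exception as exc:  # noqa: BLE001 - relabelled with stage name
                raise StageError(stage, exc) from exc
            self.manifest["stages"].setdefault(stage, {})
            self.manifest["stages"][stage]["seconds"] = round(time.time() - t0, 3)
        for name in self.manifest["outputs"]:
            self.manifest["outputs"][name] = _sha256(self.out / name)
        with open(self.out / "run_manifest.json", "w") as fh:
            json.dump(self.manifest, fh, indent=2, default=str)
        return self.manifest


def run_pipeline(config: RunConfig) -> dict:
    return Pipeline(config).run()
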