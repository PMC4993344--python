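"""Ground-truth cohort simulation for the full pipeline.

Latent-factor generative model per lobe: each CpG's beta value is a base
level plus (depending on its role) a clock signal tied to transformed age,
a shared module latent, planted age/sex/neuron-proportion effects, and
Gaussian noise, clipped to [0,1].  Module latents live at the individual
level and drive the same module in every lobe, which is what makes the
planted modules "consensus" structure; their amplitude scales with
``noise_sd`` so that in the zero-noise limit only the planted HD shift
separates samples.

All randomness flows from ``SimulationConfig.seed``; two runs with the same
config are bit-identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from comethage.clock import ClockModel, write_clock
from comethage.core_io import (
    BetaMatrix,
    CpGAnnotation,
    SampleSheet,
    ValidationError,
    write_annotation,
    write_beta_matrix,
    write_sample_sheet,
)
from comethage.enrichment import GeneSet, write_gmt

__all__ = ["SimulationConfig", "GroundTruth", "simulate_cohort", "make_synthetic_clock", "write_fixture_set"]

REGION_OF_LOBE = {
    "frontal": "frontal lobe",
    "parietal": "parietal cortex",
    "occipital": "occipital cortex",
}


@dataclass
class SimulationConfig:
    n_individuals: dict = field(default_factory=lambda: {"HD": 20, "control": 20})
    lobes: tuple = ("frontal", "parietal", "occipital")
    samples_per_individual_per_lobe: int = 1
    n_cpgs: int = 2000
    n_clock_cpgs: int = 30
    n_modules: int = 5
    module_sizes: tuple = (60, 50, 40, 40, 30)
    n_hd_modules: int = 2
    hd_effect_size: float = 0.1         # beta-unit eigenvector shift in HD
    age_effect_sd: float = 0.0015       # per-year slope scale of planted age CpGs
    sex_effect_sd: float = 0.02
    noise_sd: float = 0.02              # base residual sd; per-CpG sd ~ U(1,3)*noise_sd
    hd_age_accel_years: float = 5.0
    neuron_range: tuple = (0.2, 0.5)
    seed: int = 0
    # secondary knobs
    age_range: tuple = (30.0, 90.0)
    adult_age: float = 20.0
    module_amp_factor: float = 4.0      # module latent amplitude = factor * noise_sd
    lobe_jitter: float = 0.25           # per-lobe perturbation of the module latent
    sample_jitter: float = 0.10
    hd_neuron_shift: float = 0.0        # added to HD prop_neurons (can be negative)
    neuron_age_effect: float = 0.0      # years of DNAm age per unit prop_neurons
    frac_age_cpgs: float = 0.10         # of background CpGs
    frac_sex_cpgs: float = 0.10
    frac_neuron_cpgs: float = 0.10
    frac_unannotated: float = 0.05

    def __post_init__(self):
        self.module_sizes = tuple(self.module_sizes)
        self.lobes = tuple(self.lobes)
        if len(self.module_sizes) != self.n_modules:
            raise ValidationError("module_sizes length must equal n_modules")
        if self.n_hd_modules > self.n_modules:
            raise ValidationError("n_hd_modules exceeds n_modules")
        if sum(self.module_sizes) + self.n_clock_cpgs > self.n_cpgs:
            raise ValidationError("module_sizes + clock CpGs exceed n_cpgs")
        for name in ("hd_effect_size", "age_effect_sd", "sex_effect_sd", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if not 0 <= self.neuron_range[0] <= self.neuron_range[1] <= 1:
            raise ValidationError("neuron_range must be an interval within [0,1]")


@dataclass
class GroundTruth:
    module_label: pd.Series          # per CpG; 0 = no planted module
    is_clock: pd.Series              # per CpG
    true_clock: ClockModel
    hd_modules: list[int]
    true_accel: pd.Series            # per sample, years
    age_slope: pd.Series             # per CpG, beta units / year
    sex_shift: pd.Series             # per CpG, beta units (F - M)
    neuron_slope: pd.Series          # per CpG, beta units / unit proportion
    annotation: CpGAnnotation
    clip_rate: float
    config: SimulationConfig


def _clock_params(n: int, rng: np.random.Generator):
    """Base levels and mixed-sign per-CpG slopes on transformed age."""
    if n < 2:
        raise ValidationError("a clock needs at least 2 CpGs")
    b0 = rng.uniform(0.35, 0.65, size=n)
    signs = np.ones(n)
    signs[rng.permutation(n)[: n // 2]] = -1.0  # guaranteed mixed signs
    c = signs * rng.uniform(0.03, 0.08, size=n)
    return b0, c


def make_synthetic_clock(n_clock_cpgs: int, seed: int, adult_age: float = 20.0) -> ClockModel:
    """Reproducible linear clock with mixed-sign weights.

    Weights are w = c / sum(c^2) for per-CpG slopes c on transformed age, so
    that on a cohort generated with the same parameters the clock inverts
    the construction exactly (up to noise).
    """
    rng = np.random.default_rng(seed)
    b0, c = _clock_params(n_clock_cpgs, rng)
    w = c / np.sum(c**2)
    intercept = -float(w @ b0)
    cpg_ids = [f"cg_clk{j:04d}" for j in range(n_clock_cpgs)]
    return ClockModel(cpg_ids=cpg_ids, weights=w, intercept=intercept, adult_age=adult_age)


def _make_annotation(cpg_ids, config: SimulationConfig, rng: np.random.Generator) -> CpGAnnotation:
    """Pseudo-gene annotation exercising all representative-selection rules.

    Gene CpG-count distribution: 1 CpG 50%, 2 CpGs 25%, 3-10 CpGs 25%;
    a small fraction of CpGs stays unannotated.
    """
    n = len(cpg_ids)
    order = rng.permutation(n)
    unannotated = set(order[: int(round(config.frac_unannotated * n))])
    genes = [""] * n
    gene_idx = 0
    pool = [i for i in order if i not in unannotated]
    pos = 0
    while pos < len(pool):
        u = rng.random()
        if u < 0.5:
            size = 1
        elif u < 0.75:
            size = 2
        else:
            size = int(rng.integers(3, 11))
        gene = f"GENE{gene_idx:05d}"
        for i in pool[pos : pos + size]:
            genes[i] = gene
        gene_idx += 1
        pos += size
    chroms = [str(1 + (i % 22)) for i in range(n)]
    positions = [1000 + 137 * (i // 22) for i in range(n)]
    return CpGAnnotation(
        pd.DataFrame(
            {"cpg_id": cpg_ids, "gene_symbol": genes, "chromosome": chroms, "position": positions}
        )
    )


def simulate_cohort(config: SimulationConfig):
    """Generate per-lobe beta matrices, a sample sheet, and ground truth.

    Returns ``(betas, sheet, truth)`` with ``betas`` a dict lobe -> BetaMatrix.
    """
    clock = make_synthetic_clock(config.n_clock_cpgs, config.seed, config.adult_age)
    b0, c = _clock_params(config.n_clock_cpgs, np.random.default_rng(config.seed))
    rng = np.random.default_rng([config.seed, 0xC0DE])

    # ---- individuals -----------------------------------------------------
    ind_rows = []
    for diagnosis in sorted(config.n_individuals):
        for i in range(config.n_individuals[diagnosis]):
            ind_id = f"{diagnosis.lower()}{i:03d}"
            age = float(rng.uniform(*config.age_range))
            sex = "F" if rng.random() < 0.5 else "M"
            bank = "NewZealand" if rng.random() < 0.5 else "UCLA"
            if diagnosis == "HD":
                cag = int(rng.integers(40, 51))
                grade = int(rng.integers(1, 5))
                onset = max(10.0, age - float(rng.uniform(5, 20)))
            else:
                cag, grade, onset = np.nan, np.nan, np.nan
            accel = config.hd_age_accel_years if diagnosis == "HD" else 0.0
            ind_rows.append((ind_id, diagnosis, age, sex, bank, cag, grade, onset, accel))
    individuals = pd.DataFrame(
        ind_rows,
        columns=["individual_id", "diagnosis", "age", "sex", "bank", "cag_length",
                 "vonsattel_grade", "onset_age", "true_accel"],
    )

    # module latents at individual level (consensus across lobes)
    n_ind = len(individuals)
    latents = rng.normal(size=(config.n_modules, n_ind))

    # ---- samples ---------------------------------------------------------
    sample_rows = []
    for _, ind in individuals.iterrows():
        for lobe in config.lobes:
            for r in range(config.samples_per_individual_per_lobe):
                sid = f"{ind.individual_id}_{lobe}_{r}"
                prop = float(rng.uniform(*config.neuron_range))
                if ind.diagnosis == "HD":
                    prop = float(np.clip(prop + config.hd_neuron_shift, 0.0, 1.0))
                sample_rows.append(
                    (sid, ind.individual_id, REGION_OF_LOBE.get(lobe, lobe), lobe,
                     ind.diagnosis, ind.age, ind.sex, ind.bank, ind.cag_length,
                     ind.vonsattel_grade, ind.onset_age, prop,
                     float(rng.uniform(5, 30)), ind.true_accel)
                )
    samples = pd.DataFrame(
        sample_rows,
        columns=["sample_id", "individual_id", "region", "lobe", "diagnosis", "age",
                 "sex", "bank", "cag_length", "vonsattel_grade", "onset_age",
                 "prop_neurons", "postmortem_interval", "true_accel"],
    )

    # ---- CpG layout ------------------------------------------------------
    clock_ids = list(clock.cpg_ids)
    module_ids, module_label = [], []
    for m, size in enumerate(config.module_sizes, start=1):
        module_ids += [f"cg_m{m:02d}_{j:04d}" for j in range(size)]
        module_label += [m] * size
    n_bg = config.n_cpgs - len(clock_ids) - len(module_ids)
    bg_ids = [f"cg_bg{j:05d}" for j in range(n_bg)]
    cpg_ids = clock_ids + module_ids + bg_ids
    labels = pd.Series([0] * len(clock_ids) + module_label + [0] * n_bg, index=cpg_ids)
    is_clock = pd.Series([True] * len(clock_ids) + [False] * (len(cpg_ids) - len(clock_ids)),
                         index=cpg_ids)

    # per-CpG parameters
    n_cpg = len(cpg_ids)
    base = rng.uniform(0.35, 0.65, size=n_cpg)
    cpg_sd = config.noise_sd * rng.uniform(1.0, 3.0, size=n_cpg)
    age_slope = np.zeros(n_cpg)
    sex_shift = np.zeros(n_cpg)
    neuron_slope = np.zeros(n_cpg)
    bg_start = len(clock_ids) + len(module_ids)
    n_age = int(round(config.frac_age_cpgs * n_bg))
    n_sex = int(round(config.frac_sex_cpgs * n_bg))
    n_neu = int(round(config.frac_neuron_cpgs * n_bg))
    bg_perm = bg_start + rng.permutation(n_bg)
    age_slope[bg_perm[:n_age]] = rng.normal(0, config.age_effect_sd, size=n_age)
    sex_shift[bg_perm[n_age : n_age + n_sex]] = rng.normal(0, config.sex_effect_sd, size=n_sex)
    neuron_slope[bg_perm[n_age + n_sex : n_age + n_sex + n_neu]] = rng.normal(0, 0.1, size=n_neu)
    loadings = rng.uniform(0.5, 1.0, size=len(module_ids))
    hd_modules = list(range(1, config.n_hd_modules + 1))
    module_amp = config.module_amp_factor * config.noise_sd

    ind_pos = {iid: k for k, iid in enumerate(individuals["individual_id"])}
    age_mid = float(np.mean(config.age_range))
    prop_mid = float(np.mean(config.neuron_range))

    betas = {}
    clipped = total = 0
    for lobe in config.lobes:
        sub = samples[samples["lobe"] == lobe]
        sids = list(sub["sample_id"])
        n_s = len(sids)
        age = sub["age"].to_numpy(dtype=float)
        is_f = (sub["sex"] == "F").to_numpy(dtype=float)
        prop = sub["prop_neurons"].to_numpy(dtype=float)
        is_hd = (sub["diagnosis"] == "HD").to_numpy(dtype=float)
        accel = sub["true_accel"].to_numpy(dtype=float)
        y = clock.transform(age + accel + config.neuron_age_effect * (prop - prop_mid))

        M = np.empty((n_cpg, n_s))
        # clock block
        M[: len(clock_ids)] = b0[:, None] + np.outer(c, y)
        # module blocks
        lobe_lat = latents + config.lobe_jitter * rng.normal(size=latents.shape)
        idx = np.array([ind_pos[i] for i in sub["individual_id"]])
        row = len(clock_ids)
        for m in range(1, config.n_modules + 1):
            size = config.module_sizes[m - 1]
            lat = lobe_lat[m - 1, idx] + config.sample_jitter * rng.normal(size=n_s)
            signal = module_amp * lat
            if m in hd_modules:
                # alternate hyper-/hypo-methylation so HD modules do not
                # correlate with each other through the shared disease shift
                shift_sign = 1.0 if hd_modules.index(m) % 2 == 0 else -1.0
                signal = signal + shift_sign * config.hd_effect_size * is_hd
            load = loadings[row - len(clock_ids) : row - len(clock_ids) + size]
            M[row : row + size] = base[row : row + size, None] + np.outer(load, signal)
            row += size
        # background
        M[row:] = base[row:, None]
        # planted covariate effects and noise (all CpGs)
        M += np.outer(age_slope, age - age_mid)
        M += np.outer(sex_shift, is_f)
        M += np.outer(neuron_slope, prop - prop_mid)
        M += rng.normal(size=M.shape) * cpg_sd[:, None]

        out = np.clip(M, 0.0, 1.0)
        clipped += int(np.sum(out != M))
        total += M.size
        betas[lobe] = BetaMatrix(out, cpg_ids, sids)

    sheet = SampleSheet(samples.drop(columns="true_accel"))
    truth = GroundTruth(
        module_label=labels,
        is_clock=is_clock,
        true_clock=clock,
        hd_modules=hd_modules,
        true_accel=pd.Series(samples["true_accel"].to_numpy(), index=samples["sample_id"]),
        age_slope=pd.Series(age_slope, index=cpg_ids),
        sex_shift=pd.Series(sex_shift, index=cpg_ids),
        neuron_slope=pd.Series(neuron_slope, index=cpg_ids),
        annotation=_make_annotation(cpg_ids, config, rng),
        clip_rate=clipped / total,
        config=config,
    )
    return betas, sheet, truth


def _truth_gene_sets(truth: GroundTruth, rng: np.random.Generator) -> list[GeneSet]:
    """Gene sets derived from planted modules plus random decoys."""
    ann = truth.annotation.table
    sets = []
    for m in sorted(set(truth.module_label) - {0}):
        cpgs = truth.module_label[truth.module_label == m].index
        genes = {ann.at[c, "gene_symbol"] for c in cpgs if c in ann.index} - {""}
        if genes:
            sets.append(GeneSet(f"TRUTH:M{m:02d}", f"genes of planted module {m}", genes, "truth"))
    all_genes = sorted(set(ann["gene_symbol"]) - {""})
    for k in range(2):
        decoy = rng.choice(all_genes, size=min(40, len(all_genes)), replace=False)
        sets.append(GeneSet(f"RANDOM:{k}", "random decoy set", set(decoy), "decoy"))
    return sets


def write_fixture_set(config: SimulationConfig, out_dir) -> dict:
    """Simulate a cohort and write every pipeline input plus ground truth.

    Emits per-lobe beta TSVs, the sample sheet, the clock file, CpG
    annotation, gene sets (GMT), truth tables, and a JSON manifest listing
    paths and the seed.  Returns the manifest dict.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    betas, sheet, truth = simulate_cohort(config)
    manifest = {"seed": config.seed, "clip_rate": truth.clip_rate, "files": {}}

    for lobe, bm in betas.items():
        p = out / f"beta_{lobe}.tsv"
        write_beta_matrix(bm, p)
        manifest["files"][f"beta_{lobe}"] = str(p)
    write_sample_sheet(sheet, out / "samples.tsv")
    write_clock(truth.true_clock, out / "clock.tsv")
    write_annotation(truth.annotation, out / "annotation.tsv")
    write_gmt(_truth_gene_sets(truth, np.random.default_rng([config.seed, 0x65])),
              out / "gene_sets.gmt")
    truth_df = pd.DataFrame(
        {
            "cpg_id": truth.module_label.index,
            "module": truth.module_label.to_numpy(),
            "is_clock": truth.is_clock.to_numpy(),
            "age_slope": truth.age_slope.to_numpy(),
            "sex_shift": truth.sex_shift.to_numpy(),
            "neuron_slope": truth.neuron_slope.to_numpy(),
        }
    )
    truth_df.to_csv(out / "truth_cpgs.tsv", sep="\t", index=False)
    truth.true_accel.rename("true_accel").to_csv(out / "truth_accel.tsv", sep="\t",
                                                 index_label="sample_id")
    manifest["files"].update(
        {
            "samples": str(out / "samples.tsv"),
            "clock": str(out / "clock.tsv"),
            "annotation": str(out / "annotation.tsv"),
            "gene_sets": str(out / "gene_sets.gmt"),
            "truth_cpgs": str(out / "truth_cpgs.tsv"),
            "truth_accel": str(out / "truth_accel.tsv"),
        }
    )
    manifest["hd_modules"] = truth.hd_modules
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
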