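"""Collapse CpGs to one representative per gene and test module/gene-set overlap.

Genes with >= 3 retained CpGs are represented by the CpG with the highest
consensus intramodular connectivity (kIM, computed within the gene's own
CpG set on the signed-hybrid adjacency); 2-CpG genes by the CpG with the
higher consensus standard deviation; 1-CpG genes by their only CpG.
Per-lobe score vectors are quantile-normalized across lobes before the
component-wise consensus quantile.  Overlaps between module gene sets and
reference gene sets are evaluated with an upper-tail hypergeometric test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from comethage.core_io import CpGAnnotation, ValidationError
from comethage.network import quantile_normalize_columns

log = logging.getLogger(__name__)

__all__ = [
    "GeneSet",
    "read_gmt",
    "write_gmt",
    "gene_cpg_groups",
    "consensus_kim",
    "consensus_sd",
    "select_representatives",
    "gene_module_assignment",
    "hypergeometric_enrichment",
    "enrichment_table",
]


@dataclass
class GeneSet:
    set_id: str
    description: str
    members: frozenset
    source: str = ""

    def __post_init__(self):
        self.members = frozenset(self.members)


def read_gmt(path) -> list[GeneSet]:
    """Read gene sets from GMT: set_id <tab> description <tab> gene..."""
    sets = []
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets.append(GeneSet(parts[0], parts[1], frozenset(parts[2:]) - {""}))
    return sets


def write_gmt(gene_sets, path):
    with open(path, "w") as fh:
        for gs in gene_sets:
            fh.write("\t".join([gs.set_id, gs.description, *sorted(gs.members)]) + "\n")


def gene_cpg_groups(annotation: CpGAnnotation, retained_cpgs) -> dict[str, list[str]]:
    """Gene -> retained CpG list; unannotated CpGs are discarded.

    CpGs within each gene keep a deterministic (lexicographic) order.
    """
    retained = set(retained_cpgs)
    ann = annotation.table
    groups: dict[str, list[str]] = {}
    discarded = 0
    for cpg in sorted(retained):
        if cpg not in ann.index:
            discarded += 1
            continue
        gene = ann.at[cpg, "gene_symbol"]
        if not gene:
            discarded += 1
            continue
        groups.setdefault(gene, []).append(cpg)
    if not groups:
        raise ValidationError("no retained CpG maps to a gene")
    log.info("gene grouping: %d genes, %d CpGs discarded (unannotated)", len(groups), discarded)
    return groups


def _consensus_scores(per_lobe: dict[str, np.ndarray], q: float) -> np.ndarray:
    """Quantile-normalize per-lobe score vectors, then component-wise q-quantile."""
    M = np.column_stack(list(per_lobe.values()))
    normed = quantile_normalize_columns(M)
    return np.quantile(normed, q, axis=1)


def consensus_kim(
    adjacency_per_lobe: dict[str, np.ndarray],
    cpg_index: dict[str, int],
    gene_cpgs,
    q: float = 0.0,
) -> pd.Series:
    """Consensus intramodular connectivity for the CpGs of one gene.

    ``adjacency_per_lobe`` holds the full signed-hybrid adjacency per lobe;
    ``cpg_index`` maps CpG id to its row.  kIM_i is the sum of adjacencies
    from CpG i to the other CpGs of the same gene.
    """
    gene_cpgs = list(gene_cpgs)
    if len(gene_cpgs) < 3:
        raise ValidationError("consensus kIM needs >= 3 CpGs (use the sd rule)")
    rows = [cpg_index[c] for c in gene_cpgs]
    per_lobe = {}
    for lobe, A in adjacency_per_lobe.items():
        sub = A[np.ix_(rows, rows)]
        per_lobe[lobe] = sub.sum(axis=1)  # zero diagonal: sum over j != i
    return pd.Series(_consensus_scores(per_lobe, q), index=gene_cpgs)


def consensus_sd(
    beta_per_lobe: dict[str, pd.DataFrame],
    cpg_pair,
    q: float = 0.0,
) -> pd.Series:
    """Consensus standard deviation for a 2-CpG gene."""
    cpg_pair = list(cpg_pair)
    if len(cpg_pair) != 2:
        raise ValidationError("consensus sd applies to exactly 2 CpGs")
    per_lobe = {}
    for lobe, df in beta_per_lobe.items():
        per_lobe[lobe] = df.loc[cpg_pair].to_numpy(dtype=float).std(axis=1, ddof=1)
    return pd.Series(_consensus_scores(per_lobe, q), index=cpg_pair)


def select_representatives(
    groups: dict[str, list[str]],
    adjacency_per_lobe: dict[str, np.ndarray],
    cpg_index: dict[str, int],
    beta_per_lobe: dict[str, pd.DataFrame],
    q: float = 0.0,
) -> pd.DataFrame:
    """One representative CpG per gene (columns: gene, cpg_id, rule, score).

    Argmax ties break lexicographically on cpg_id (groups are pre-sorted and
    the first maximal score wins).
    """
    records = []
    for gene in sorted(groups):
        cpgs = groups[gene]
        if len(cpgs) == 1:
            records.append((gene, cpgs[0], "single", np.nan))
        elif len(cpgs) == 2:
            scores = consensus_sd(beta_per_lobe, cpgs, q)
            best = scores.idxmax()
            records.append((gene, best, "sd2", float(scores[best])))
        else:
            scores = consensus_kim(adjacency_per_lobe, cpg_index, cpgs, q)
            best = scores.idxmax()
            records.append((gene, best, "kim3plus", float(scores[best])))
    return pd.DataFrame(records, columns=["gene", "cpg_id", "rule", "score"])


def gene_module_assignment(representatives: pd.DataFrame, module_labels: dict[str, int]) -> pd.DataFrame:
    """Each gene inherits its representative CpG's module label (0 = grey)."""
    missing = [c for c in representatives["cpg_id"] if c not in module_labels]
    if missing:
        raise ValidationError(f"representatives without a module label: {missing[:5]}")
    out = representatives.copy()
    out["module"] = [module_labels[c] for c in out["cpg_id"]]
    return out


def hypergeometric_enrichment(module_genes, gene_set: GeneSet, universe) -> dict:
    """Upper-tail hypergeometric p of observing >= overlap set genes in a module.

    The gene set is intersected with the universe first.
    """
    universe = set(universe)
    if not universe:
        raise ValidationError("empty universe")
    module_genes = set(module_genes) & universe
    set_genes = gene_set.members & universe
    overlap = len(module_genes & set_genes)
    N, K, n = len(universe), len(set_genes), len(module_genes)
    p = float(hypergeom.sf(overlap - 1, N, K, n)) if overlap > 0 else float(
        hypergeom.sf(-1, N, K, n)
    )
    return {
        "set_id": gene_set.set_id,
        "description": gene_set.description,
        "source": gene_set.source,
        "overlap": overlap,
        "module_genes": n,
        "set_genes": K,
        "universe": N,
        "p": min(max(p, np.nextafter(0, 1)), 1.0),
    }


def enrichment_table(
    assignments: pd.DataFrame,
    gene_sets,
    universe=None,
    include_grey: bool = False,
) -> pd.DataFrame:
    """Module x gene-set enrichment rows, sorted by p within module.

    Universe defaults to all represented genes.
    """
    if universe is None:
        universe = set(assignments["gene"])
    rows = []
    for module, sub in assignments.groupby("module"):
        if module == 0 and not include_grey:
            continue
        genes = set(sub["gene"])
        for gs in gene_sets:
            row = hypergeometric_enrichment(genes, gs, universe)
            row["module"] = int(module)
            rows.append(row)
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    cols = ["module", "set_id", "description", "source", "overlap", "module_genes", "set_genes", "universe", "p"]
    return df[cols].sort_values(["module", "p"]).reset_index(drop=True)
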