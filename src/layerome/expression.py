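"""Differential expression between two condition groups.

Genes are filtered with a two-sided pooled-variance (Student's) two-sample
t-test at a raw significance level (no multiplicity correction at this
stage; family-wise control is applied later, to annotation terms only).
Differential genes are then split into an up- and a down-regulated cluster
by deterministic 2-medoid clustering of their standardized expression
profiles under correlation distance, with genes that fail to correlate with
either cluster centroid left ``unclustered``.

Direction convention: ``up`` means higher mean expression in group A, the
reference ("recurrent-like") condition, i.e. ``mean_diff = mean(A) - mean(B) > 0``.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

DIRECTIONS = ("up", "down", "unclustered", "not_de")


@dataclass
class ExpressionDataset:
    """Gene x sample expression matrix with a two-level condition label.

    ``values`` is a DataFrame indexed by gene id with sample ids as columns;
    ``condition`` maps each sample id to one of exactly two group labels.
    ``group_a`` names the reference level used for the direction sign.
    """

    values: pd.DataFrame
    condition: pd.Series
    group_a: str = field(default="")

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            raise ValueError("duplicate gene ids in expression matrix")
        if self.values.columns.duplicated().any():
            raise ValueError("duplicate sample ids in expression matrix")
        self.condition = self.condition.reindex(self.values.columns)
        if self.condition.isna().any():
            missing = list(self.condition.index[self.condition.isna()])
            raise ValueError(f"samples without condition label: {missing}")
        levels = sorted(self.condition.unique())
        if len(levels) != 2:
            raise ValueError(f"condition must have exactly 2 levels, got {levels}")
        counts = self.condition.value_counts()
        if counts.min() < 2:
            raise ValueError("each condition group needs >= 2 samples")
        if not self.group_a:
            self.group_a = levels[0]
        if self.group_a not in levels:
            raise ValueError(f"group_a {self.group_a!r} not a condition level")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def group_b(self) -> str:
        return next(g for g in sorted(self.condition.unique()) if g != self.group_a)

    def group_columns(self, group: str) -> list[str]:
        return list(self.condition.index[self.condition == group])


def _pooled_t(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized equal-variance two-sample t along the last axis.

    Degenerate convention for zero pooled variance: t = 0, p = 1 when the
    group means are equal, otherwise t = +/-inf and p = 0.
    """
    na, nb = a.shape[-1], b.shape[-1]
    mean_a, mean_b = a.mean(axis=-1), b.mean(axis=-1)
    var_a = a.var(axis=-1, ddof=1)
    var_b = b.var(axis=-1, ddof=1)
    df = na + nb - 2
    sp2 = ((na - 1) * var_a + (nb - 1) * var_b) / df
    se = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    diff = mean_a - mean_b
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / se
    p = 2.0 * stats.t.sf(np.abs(t), df)
    zero_se = se == 0
    if np.any(zero_se):
        equal = zero_se & (diff == 0)
        unequal = zero_se & (diff != 0)
        t = np.where(equal, 0.0, t)
        p = np.where(equal, 1.0, p)
        with np.errstate(invalid="ignore"):
            t = np.where(unequal, np.sign(diff) * np.inf, t)
        p = np.where(unequal, 0.0, p)
    return t, p


def student_t_test(dataset: ExpressionDataset, gene: str) -> tuple[float, float]:
    """Two-sided pooled-variance t-test for one gene (group A vs group B)."""
    if gene not in dataset.values.index:
        raise KeyError(f"gene {gene!r} not in dataset")
    a = dataset.values.loc[gene, dataset.group_columns(dataset.group_a)].to_numpy(float)
    b = dataset.values.loc[gene, dataset.group_columns(dataset.group_b)].to_numpy(float)
    t, p = _pooled_t(a[None, :], b[None, :])
    return float(t[0]), float(p[0])


@dataclass
class DifferentialResult:
    """Per-gene t statistics, p-values, mean differences and directions.

    ``table`` columns: t, p_value, mean_diff, direction. A gene's direction
    is in {up, down, unclustered} iff p_value < alpha, else ``not_de``.
    """

    table: pd.DataFrame
    alpha: float

    @property
    def de_genes(self) -> list[str]:
        return list(self.table.index[self.table["p_value"] < self.alpha])

    def genes_with_direction(self, *directions: str) -> list[str]:
        return list(self.table.index[self.table["direction"].isin(directions)])

    @property
    def direction_map(self) -> dict[str, str]:
        return self.table["direction"].to_dict()

    def counts(self) -> dict[str, int]:
        de = self.table["p_value"] < self.alpha
        d = self.table.loc[de, "direction"]
        return {
            "total_de": int(de.sum()),
            "up": int((d == "up").sum()),
            "down": int((d == "down").sum()),
            "unclustered": int((d == "unclustered").sum()),
        }


def select_de_genes(dataset: ExpressionDataset, alpha: float = 0.05) -> DifferentialResult:
    """Flag genes with raw two-sided t-test p < alpha as differential.

    Directions are pending: DE genes are provisionally ``unclustered`` until
    :func:`cluster_directions` assigns up/down labels.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    a = dataset.values[dataset.group_columns(dataset.group_a)].to_numpy(float)
    b = dataset.values[dataset.group_columns(dataset.group_b)].to_numpy(float)
    t, p = _pooled_t(a, b)
    mean_diff = a.mean(axis=1) - b.mean(axis=1)
    table = pd.DataFrame(
        {"t": t, "p_value": p, "mean_diff": mean_diff},
        index=dataset.values.index,
    )
    table["direction"] = np.where(table["p_value"] < alpha, "unclustered", "not_de")
    n_de = int((table["p_value"] < alpha).sum())
    logger.info("DE filter: %d of %d genes at alpha=%g", n_de, len(table), alpha)
    return DifferentialResult(table=table, alpha=alpha)


def _zscore_profiles(values: pd.DataFrame) -> np.ndarray:
    x = values.to_numpy(float)
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True, ddof=0)
    sd = np.where(sd == 0, 1.0, sd)
    return (x - mu) / sd


def cluster_directions(
    dataset: ExpressionDataset,
    de_result: DifferentialResult,
    corr_floor: float = 0.0,
) -> DifferentialResult:
    """Assign up/down/unclustered directions to DE genes.

    Standardized (per-gene z-score) profiles of the DE genes are split into
    two clusters by 2-medoid partitioning under correlation distance.
    Medoids are seeded from the genes with the most extreme ``mean_diff``
    (maximum and minimum), so the partition is deterministic. Each cluster
    is labeled up or down by the sign of its centroid's group contrast
    (mean over group-A samples minus mean over group-B samples). A DE gene
    whose profile correlation with its own cluster centroid is <= the floor
    (default 0, so orthogonal or anti-correlated profiles are dropped) is
    labeled ``unclustered``. With fewer than 2 DE genes the direction is the
    sign of ``mean_diff`` directly.
    """
    table = de_result.table.copy()
    de_mask = table["p_value"] < de_result.alpha
    de_genes = list(table.index[de_mask])
    if len(de_genes) < 2:
        for g in de_genes:
            table.loc[g, "direction"] = "up" if table.loc[g, "mean_diff"] >= 0 else "down"
        return DifferentialResult(table=table, alpha=de_result.alpha)

    z = _zscore_profiles(dataset.values.loc[de_genes])
    n_genes = len(de_genes)
    # correlation of z-scored rows
    corr = np.corrcoef(z) if n_genes > 1 else np.ones((1, 1))
    corr = np.nan_to_num(corr, nan=0.0)
    dist = 1.0 - corr

    md = table.loc[de_genes, "mean_diff"].to_numpy()
    medoids = [int(np.argmax(md)), int(np.argmin(md))]
    if medoids[0] == medoids[1]:
        medoids[1] = (medoids[0] + 1) % n_genes

    assign = np.zeros(n_genes, dtype=int)
    for _ in range(100):
        d0, d1 = dist[:, medoids[0]], dist[:, medoids[1]]
        new_assign = (d1 < d0).astype(int)  # ties go to cluster 0
        new_medoids = list(medoids)
        for k in (0, 1):
            members = np.flatnonzero(new_assign == k)
            if members.size == 0:
                continue
            within = dist[np.ix_(members, members)].sum(axis=1)
            # tie-break by gene id for determinism
            order = sorted(range(members.size), key=lambda i: (within[i], de_genes[members[i]]))
            new_medoids[k] = int(members[order[0]])
        if new_medoids == medoids and np.array_equal(new_assign, assign):
            break
        medoids, assign = new_medoids, new_assign

    cols_a = [dataset.sample_ids.index(s) for s in dataset.group_columns(dataset.group_a)]
    cols_b = [dataset.sample_ids.index(s) for s in dataset.group_columns(dataset.group_b)]
    labels = {}
    centroids = {}
    for k in (0, 1):
        members = np.flatnonzero(assign == k)
        if members.size == 0:
            continue
        centroid = z[members].mean(axis=0)
        centroids[k] = centroid
        contrast = centroid[cols_a].mean() - centroid[cols_b].mean()
        if contrast == 0:  # degenerate: fall back to the medoid's own contrast
            contrast = md[medoids[k]]
        labels[k] = "up" if contrast > 0 else "down"

    for i, gene in enumerate(de_genes):
        k = int(assign[i])
        if k not in centroids:
            table.loc[gene, "direction"] = "up" if md[i] >= 0 else "down"
            continue
        c = centroids[k]
        denom = np.linalg.norm(z[i]) * np.linalg.norm(c)
        r = float(np.clip(z[i] @ c / denom, -1.0, 1.0)) if denom > 0 else 0.0
        table.loc[gene, "direction"] = labels[k] if r > corr_floor else "unclustered"

    counts = DifferentialResult(table=table, alpha=de_result.alpha).counts()
    logger.info(
        "direction clustering: %(up)d up, %(down)d down, %(unclustered)d unclustered", counts
    )
    return DifferentialResult(table=table, alpha=de_result.alpha)


# ---------------------------------------------------------------------------
# I/O: expression TSV as written by synthdata, per-gene result TSV
# ---------------------------------------------------------------------------

def read_expression_tsv(path) -> ExpressionDataset:
    """Read a gene x sample TSV with a ``#condition`` line after the header."""
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        cond_line = fh.readline().rstrip("\n").split("\t")
        if cond_line[0] != "#condition":
            raise ValueError(f"{path}: expected '#condition' line after header")
        body = fh.read()
    sample_ids = header[1:]
    condition = pd.Series(cond_line[1:], index=sample_ids)
    values = pd.read_csv(
        io.StringIO(body), sep="\t", header=None, index_col=0, names=[header[0], *sample_ids]
    )
    values.index.name = header[0]
    return ExpressionDataset(values=values, condition=condition)


def write_expression_tsv(dataset: ExpressionDataset, path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("gene_id\t" + "\t".join(dataset.sample_ids) + "\n")
        fh.write("#condition\t" + "\t".join(dataset.condition[s] for s in dataset.sample_ids) + "\n")
        for gene, row in dataset.values.iterrows():
            fh.write(gene + "\t" + "\t".join(format(v, ".6g") for v in row) + "\n")


def write_de_tsv(result: DifferentialResult, path) -> None:
    out = result.table.copy()
    out.index.name = "gene"
    out.to_csv(path, sep="\t", float_format="%.6g", lineterminator="\n")
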