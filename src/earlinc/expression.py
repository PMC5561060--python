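"""Expression profiling: FPKM, tissue specificity, differential expression,
correlation, sample-structure checks and relative qRT-PCR quantification.

The DE screen is a deliberately simple, documented stand-in for a
negative-binomial GLM: median-of-ratios size-factor normalization, a
moderated t-test on log2(normalized + 1) (per-gene variances shrunk toward
the cohort median, empirical-Bayes style — at 3 replicates per group a pure
per-gene test has almost no power after FDR adjustment), and
Benjamini-Hochberg correction. A plain Welch t and arbitrary callables are
available so a heavier fit can be substituted without touching callers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.stats as st
from scipy.spatial.distance import pdist, squareform
from statsmodels.stats.multitest import multipletests


class ConstantInputError(ValueError):
    """Pearson correlation is undefined for a constant vector."""


@dataclass(frozen=True)
class SampleInfo:
    sample_id: str
    tissue: str
    stage: str
    replicate: int


@dataclass
class ExpressionMatrix:
    """genes x samples expression values with a unit tag and sample sheet.

    ``unit`` is exactly one of ``counts`` or ``fpkm``. ``gene_lengths``
    (bp per gene) is required to convert counts to FPKM.
    """

    values: pd.DataFrame
    unit: str
    gene_lengths: pd.Series | None = None
    samples: list[SampleInfo] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.unit not in ("counts", "fpkm"):
            raise ValueError(f"unit must be counts or fpkm, got {self.unit!r}")
        if (self.values.values < 0).any():
            raise ValueError("expression values must be non-negative")
        if self.unit == "counts" and self.gene_lengths is not None:
            lens = self.gene_lengths.reindex(self.values.index)
            if lens.isna().any():
                missing = lens[lens.isna()].index.tolist()[:5]
                raise ValueError(f"gene_lengths missing for genes: {missing}")
            if (lens < 1).any():
                raise ValueError("gene_lengths must be >= 1")
        if self.samples:
            keys = {(s.tissue, s.stage, s.replicate) for s in self.samples}
            if len(keys) != len(self.samples):
                raise ValueError("(tissue, stage, replicate) must be unique per sample")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def to_tsv(self, path: str | Path) -> None:
        self.values.to_csv(path, sep="\t", index_label="gene_id")

    @classmethod
    def from_tsv(
        cls,
        path: str | Path,
        unit: str,
        gene_lengths: pd.Series | None = None,
        sample_sheet: str | Path | None = None,
    ) -> "ExpressionMatrix":
        values = pd.read_csv(path, sep="\t", index_col=0)
        samples = []
        if sample_sheet is not None:
            sheet = pd.read_csv(sample_sheet, sep="\t")
            samples = [
                SampleInfo(r.sample_id, r.tissue, r.stage, int(r.replicate))
                for r in sheet.itertuples(index=False)
            ]
        return cls(values=values, unit=unit, gene_lengths=gene_lengths, samples=samples)


def write_sample_sheet(samples: Sequence[SampleInfo], path: str | Path) -> None:
    pd.DataFrame(
        [
            {"sample_id": s.sample_id, "tissue": s.tissue, "stage": s.stage,
             "replicate": s.replicate}
            for s in samples
        ]
    ).to_csv(path, sep="\t", index=False)


def compute_fpkm(counts: ExpressionMatrix) -> ExpressionMatrix:
    """counts -> FPKM: ``counts * 1e9 / (library_size * gene_length)``.

    Library size is the per-sample column sum; a zero library size is an
    error naming the sample.
    """
    if counts.unit != "counts":
        raise ValueError("compute_fpkm expects a counts matrix")
    if counts.gene_lengths is None:
        raise ValueError("compute_fpkm requires gene_lengths")
    libsize = counts.values.sum(axis=0)
    zero = libsize[libsize == 0]
    if len(zero):
        raise ValueError(f"zero library size in sample(s): {list(zero.index)}")
    lens = counts.gene_lengths.reindex(counts.values.index)
    fpkm = counts.values.mul(1e9).div(libsize, axis=1).div(lens, axis=0)
    return ExpressionMatrix(values=fpkm, unit="fpkm", samples=counts.samples)


def specificity_count(
    panel: ExpressionMatrix, threshold: float = 1.0
) -> tuple[pd.Series, float]:
    """Per-gene count of panel samples with FPKM >= threshold (inclusive).

    Also returns the fraction of genes expressed in no sample at all — the
    "silent everywhere" statistic of the multi-tissue panel comparison.
    """
    if panel.unit != "fpkm":
        raise ValueError("specificity_count expects an FPKM matrix")
    counts = (panel.values >= threshold).sum(axis=1)
    frac_silent = float((counts == 0).mean()) if len(counts) else 0.0
    return counts, frac_silent


# ---------------------------------------------------------------------------
# Differential expression

@dataclass(frozen=True)
class DEResult:
    gene_id: str
    log2_fold_change: float
    p_value: float
    adj_p: float
    significant: bool


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors (ratios to the per-gene geometric mean,
    computed over genes positive in every sample)."""
    positive = counts[(counts > 0).all(axis=1)]
    if positive.empty:
        raise ValueError("no gene has positive counts in all samples")
    log_geo = np.log(positive).mean(axis=1)
    ratios = np.log(positive).sub(log_geo, axis=0)
    return np.exp(ratios.median(axis=0))


def moderated_t_pvalues(
    xa: np.ndarray, xb: np.ndarray, prior_df: float = 8.0
) -> np.ndarray:
    """Two-sided moderated t on rows of two group matrices.

    Per-gene pooled variances are shrunk toward the cohort median with
    ``prior_df`` pseudo-observations; the statistic is referred to a t
    distribution with prior_df + residual df. Genes with a zero moderated
    variance and equal means get p = 1.
    """
    na, nb = xa.shape[1], xb.shape[1]
    dg = na + nb - 2
    sg2 = (xa.var(axis=1, ddof=1) * (na - 1) + xb.var(axis=1, ddof=1) * (nb - 1)) / dg
    s02 = float(np.median(sg2))
    s2 = (prior_df * s02 + dg * sg2) / (prior_df + dg)
    diff = xb.mean(axis=1) - xa.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = diff / np.sqrt(s2 * (1.0 / na + 1.0 / nb))
    p = 2.0 * st.t.sf(np.abs(t), df=prior_df + dg)
    p[np.isnan(t) & np.isclose(diff, 0.0)] = 1.0
    p[np.isnan(p)] = 1.0
    return p


def welch_t_pvalues(xa: np.ndarray, xb: np.ndarray) -> np.ndarray:
    """Plain per-gene two-sided Welch t on rows of two group matrices."""
    with np.errstate(invalid="ignore", divide="ignore"):
        res = st.ttest_ind(xa, xb, axis=1, equal_var=False)
    p = np.asarray(res.pvalue)
    nanmask = np.isnan(p)
    p[nanmask & np.isclose(xa.mean(axis=1), xb.mean(axis=1))] = 1.0
    p[np.isnan(p)] = 1.0
    return p


def de_screen(
    counts: ExpressionMatrix,
    group_a: Sequence[str],
    group_b: Sequence[str],
    alpha: float = 0.05,
    min_fold: float = 2.0,
    pseudocount: float = 1.0,
    method: str | Callable[[np.ndarray, np.ndarray], float] = "moderated",
) -> pd.DataFrame:
    """Two-group differential-expression screen.

    Median-of-ratios normalization, a two-sided test on log2(normalized +
    1) (``method``: "moderated" t with variance shrinkage, the default;
    "welch" for a pure per-gene Welch t; or a callable ``f(a, b) -> p``),
    BH adjustment across tested genes, and a call of ``significant`` when
    adj_p < alpha and |log2FC| >= log2(min_fold). All-zero genes are
    reported with p = NaN (untested), never dropped.
    """
    if counts.unit != "counts":
        raise ValueError("de_screen expects a counts matrix")
    ga, gb = list(group_a), list(group_b)
    if set(ga) & set(gb):
        raise ValueError("groups overlap")
    if len(ga) < 2 or len(gb) < 2:
        raise ValueError("need >= 2 samples per group")
    sub = counts.values[ga + gb]
    sf = size_factors(sub)
    norm = sub.div(sf, axis=1)
    log = np.log2(norm + pseudocount)
    mean_a = norm[ga].mean(axis=1)
    mean_b = norm[gb].mean(axis=1)
    lfc = np.log2((mean_b + pseudocount) / (mean_a + pseudocount))
    tested = (sub.sum(axis=1) > 0).to_numpy()
    pvals = np.full(len(sub), np.nan)
    if callable(method):
        for i, g in enumerate(sub.index):
            if tested[i]:
                pvals[i] = method(log.loc[g, ga].to_numpy(), log.loc[g, gb].to_numpy())
    else:
        xa = log[ga].to_numpy()
        xb = log[gb].to_numpy()
        if method == "moderated":
            p = moderated_t_pvalues(xa, xb)
        elif method == "welch":
            p = welch_t_pvalues(xa, xb)
        else:
            raise ValueError(f"unknown method {method!r}")
        pvals[tested] = p[tested]
    adj = np.full(len(sub), np.nan)
    mask = ~np.isnan(pvals)
    if mask.any():
        adj[mask] = multipletests(pvals[mask], method="fdr_bh")[1]
    min_lfc = np.log2(min_fold)
    sig = mask & (adj < alpha) & (np.abs(lfc.to_numpy()) >= min_lfc)
    return pd.DataFrame(
        {
            "gene_id": sub.index,
            "log2_fold_change": lfc.to_numpy(),
            "p_value": pvals,
            "adj_p": adj,
            "significant": sig,
        }
    ).set_index("gene_id")


def bh_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    return multipletests(np.asarray(pvals, dtype=float), method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# Correlation

def correlate(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Pearson R with a two-sided t-test p-value.

    Raises :class:`ConstantInputError` for a constant vector (R undefined,
    never reported as 0).
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape or xa.ndim != 1:
        raise ValueError("vectors must be 1-D and equal length")
    if len(xa) < 3:
        raise ValueError("need n >= 3")
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        raise ConstantInputError("constant vector: correlation undefined")
    r, p = st.pearsonr(xa, ya)
    return float(r), float(p)


# ---------------------------------------------------------------------------
# Sample structure

@dataclass
class SampleStructure:
    distances: pd.DataFrame
    linkage: np.ndarray
    variance_fractions: np.ndarray
    pc_scores: pd.DataFrame

    def cut(self, k: int) -> dict[str, int]:
        labels = sch.fcluster(self.linkage, t=k, criterion="maxclust")
        return dict(zip(self.distances.index, (int(v) for v in labels)))


def sample_structure(fpkm: ExpressionMatrix) -> SampleStructure:
    """Pairwise Euclidean distances on log2(FPKM+1), an average-linkage
    dendrogram, and PCA variance fractions (samples as observations,
    centering only)."""
    if fpkm.unit != "fpkm":
        raise ValueError("sample_structure expects an FPKM matrix")
    if fpkm.values.shape[1] < 3:
        raise ValueError("need >= 3 samples")
    X = np.log2(fpkm.values.to_numpy().T + 1.0)  # samples x genes
    ids = fpkm.sample_ids
    dvec = pdist(X, metric="euclidean")
    dist = pd.DataFrame(squareform(dvec), index=ids, columns=ids)
    Z = sch.linkage(dvec, method="average")
    Xc = X - X.mean(axis=0, keepdims=True)
    _, s, vt = np.linalg.svd(Xc, full_matrices=False)
    var = s**2
    total = var.sum()
    fractions = var / total if total > 0 else var
    scores = Xc @ vt.T
    pc_cols = [f"PC{i+1}" for i in range(scores.shape[1])]
    return SampleStructure(
        distances=dist,
        linkage=Z,
        variance_fractions=fractions,
        pc_scores=pd.DataFrame(scores, index=ids, columns=pc_cols),
    )


# ---------------------------------------------------------------------------
# qRT-PCR relative quantification

def delta_delta_ct(
    ct: pd.DataFrame, calibrator: str, target: str = "target", reference: str = "reference"
) -> pd.Series:
    """2^-ddCt relative expression per sample.

    ``ct`` is indexed by sample with a target and a reference (housekeeping,
    e.g. Gapdh) Ct column. dCt = Ct_target - Ct_ref; ddCt = dCt_sample -
    dCt_calibrator; the calibrator sample comes out exactly 1.
    """
    for col in (target, reference):
        if col not in ct.columns:
            raise ValueError(f"Ct table lacks column {col!r}")
        missing = ct.index[ct[col].isna()].tolist()
        if missing:
            raise ValueError(f"missing Ct for sample(s) {missing} in column {col!r}")
    if calibrator not in ct.index:
        raise ValueError(f"calibrator sample {calibrator!r} absent from Ct table")
    dct = ct[target] - ct[reference]
    ddct = dct - dct.loc[calibrator]
    return np.power(2.0, -ddct)
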