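"""Grade-association screening and signature construction.

The discovery cohort carries an ordinal WHO grade (I–IV) per sample.  Each
retained feature is tested for monotone association with grade by Spearman
rank correlation; p-values are Benjamini–Hochberg adjusted over all tested
features jointly, and genes from a restriction set (the ion-channel list)
whose features pass the adjusted threshold enter the signature with weight
+1 (expression rises with grade) or −1 (falls with grade).
"""

from __future__ import annotations

import itertools
import logging
import math

import numpy as np
import pandas as pd
from scipy import stats

from .containers import SEX_CHROMOSOMES, ExpressionMatrix, Signature, normalize_chromosome

logger = logging.getLogger(__name__)

_TINY_P = 1e-300  # keep p-values in (0, 1]


class ConstantInputError(ValueError):
    """A correlation/test input has zero variance."""


# ---------------------------------------------------------------------------
# elementary statistics
# ---------------------------------------------------------------------------

def spearman_rho(x, y, *, exact_max_n: int = 9) -> tuple[float, float]:
    """Spearman rank correlation with a two-sided p-value.

    Ties receive average ranks and the p-value uses the t approximation on
    ranks; for n ≤ ``exact_max_n`` with no ties in either vector the p-value
    is computed exactly by enumerating all rank permutations.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d vectors of equal length")
    n = x.size
    if n < 4:
        raise ValueError("need at least 4 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ConstantInputError("constant vector: Spearman rho undefined")

    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])

    no_ties = len(np.unique(x)) == n and len(np.unique(y)) == n
    if no_ties and n <= exact_max_n:
        p = _exact_spearman_p(rx, ry, rho)
    else:
        p = _spearman_t_p(rho, n)
    return rho, p


def _spearman_t_p(rho: float, n: int) -> float:
    r = min(max(rho, -1.0), 1.0)
    if abs(r) == 1.0:
        return _TINY_P
    t = r * math.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return float(min(max(p, _TINY_P), 1.0))


def _exact_spearman_p(rx: np.ndarray, ry: np.ndarray, rho: float) -> float:
    """Two-sided exact p by full enumeration of rank pairings (no ties)."""
    n = rx.size
    perms = np.array(list(itertools.permutations(range(1, n + 1))), dtype=float)
    denom = n * (n * n - 1)
    d2 = ((perms - rx[None, :]) ** 2).sum(axis=1)
    rho_perm = 1.0 - 6.0 * d2 / denom
    return float(np.mean(np.abs(rho_perm) >= abs(rho) - 1e-12))


def bh_adjust(p) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, clipped at 1."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return stats.false_discovery_control(p, method="bh")


def enrichment_test(k_in_selected: int, n_selected: int, K_in_universe: int, N_universe: int) -> float:
    """One-tailed Fisher (hypergeometric upper tail) enrichment p-value.

    Probability of drawing ≥ ``k_in_selected`` marked items when
    ``n_selected`` items are drawn without replacement from a universe of
    ``N_universe`` containing ``K_in_universe`` marked items.
    """
    k, n, K, N = int(k_in_selected), int(n_selected), int(K_in_universe), int(N_universe)
    if min(k, n, K, N) < 0 or k > min(n, K) or n > N or K > N:
        raise ValueError(f"inconsistent contingency counts (k={k}, n={n}, K={K}, N={N})")
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def compare_rho_distributions(rho_a, rho_b) -> tuple[float, float]:
    """Welch two-sample t-test of mean rho difference (group a minus group b).

    Used to ask whether one gene class (e.g. ion channels) is shifted toward
    more negative grade correlations than the rest of the transcriptome.
    """
    a = np.asarray(rho_a, dtype=float)
    b = np.asarray(rho_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        if a[0] == b[0]:
            return 0.0, 1.0
        raise ConstantInputError("both groups constant with different values")
    t, p = stats.ttest_ind(a, b, equal_var=False)
    if not np.isfinite(t):
        raise ConstantInputError("degenerate zero-variance inputs")
    return float(t), float(p)


# ---------------------------------------------------------------------------
# feature filters
# ---------------------------------------------------------------------------

def filter_by_presence(calls: pd.DataFrame, min_fraction: float = 2.0 / 3.0) -> pd.Index:
    """Feature ids whose present-call fraction is ≥ ``min_fraction``."""
    if not 0 < min_fraction <= 1:
        raise ValueError("min_fraction must lie in (0, 1]")
    if calls.size == 0:
        raise ValueError("empty call matrix")
    frac = calls.astype(bool).mean(axis=1)
    kept = calls.index[frac >= min_fraction - 1e-12]
    logger.info("presence filter: %d of %d features retained", len(kept), len(calls))
    return kept


def filter_sex_chromosomes(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Drop features annotated to chromosome X or Y.

    Features with missing chromosome annotation are retained with a warning
    (fail-open on metadata, fail-closed on data).
    """
    if matrix.annotation is None or "chromosome" not in matrix.annotation.columns:
        logger.warning("no chromosome annotation: sex-chromosome filter is a no-op")
        return matrix
    chrom = matrix.annotation["chromosome"].map(normalize_chromosome)
    unknown = int((chrom == "").sum())
    if unknown:
        logger.warning("%d feature(s) lack chromosome annotation; retained", unknown)
    keep = ~chrom.isin(SEX_CHROMOSOMES)
    dropped = int((~keep).sum())
    if dropped:
        logger.info("sex-chromosome filter: removed %d feature(s)", dropped)
    return matrix.subset_features(matrix.feature_ids[keep])


def collapse_probes_to_genes(
    matrix: ExpressionMatrix, mapping: pd.Series | None = None
) -> ExpressionMatrix:
    """Collapse probe-level rows to one row per gene.

    Multi-probe genes are summarized by the geometric mean on the linear
    scale, i.e. the arithmetic mean of log2 values.  ``mapping`` is a
    feature_id → gene_symbol Series; by default the annotation's gene
    symbols are used.  Every feature must map to a non-empty gene.
    """
    if mapping is None:
        if matrix.annotation is None or "gene_symbol" not in matrix.annotation.columns:
            raise ValueError("no probe→gene mapping available")
        mapping = matrix.gene_symbols()
    mapping = pd.Series(mapping)
    missing = matrix.feature_ids.difference(mapping.index)
    if len(missing):
        raise ValueError(f"mapping does not cover {len(missing)} feature(s)")
    genes = mapping.loc[matrix.feature_ids].astype(str)
    if (genes == "").any():
        raise ValueError("empty gene symbol in probe→gene mapping")

    collapsed = matrix.values.groupby(genes.to_numpy()).mean()
    collapsed.index.name = "gene_symbol"
    annotation = None
    if matrix.annotation is not None:
        ann = matrix.annotation.copy()
        ann["__gene"] = genes.to_numpy()
        agg: dict[str, object] = {}
        if "chromosome" in ann.columns:
            agg["chromosome"] = ("chromosome", "first")
        if "is_ion_channel" in ann.columns:
            agg["is_ion_channel"] = ("is_ion_channel", "any")
        if agg:
            annotation = ann.groupby("__gene").agg(**agg)
            annotation["gene_symbol"] = annotation.index
            annotation = annotation.loc[collapsed.index]
    logger.info(
        "collapsed %d features to %d genes", matrix.n_features, collapsed.shape[0]
    )
    return ExpressionMatrix(collapsed, annotation)


# ---------------------------------------------------------------------------
# grade association and signature construction
# ---------------------------------------------------------------------------

def correlate_with_grade(matrix: ExpressionMatrix, grades: pd.Series) -> pd.DataFrame:
    """Spearman correlation of every feature with ordinal tumor grade.

    Returns a DataFrame indexed by feature id with columns ``gene_symbol``,
    ``rho``, ``p_raw``, ``p_adj`` (BH over all tested features jointly) and
    ``direction`` (sign of rho).  Constant features are excluded from the
    table; their ids are available as ``result.attrs['excluded_features']``.
    """
    grades = pd.Series(grades)
    missing = matrix.sample_ids.difference(grades.index)
    if len(missing):
        raise ValueError(f"grades missing for {len(missing)} sample(s)")
    g = grades.loc[matrix.sample_ids].to_numpy(dtype=float)
    if len(np.unique(g)) < 2:
        raise ValueError("need at least 2 distinct grades")
    n = matrix.n_samples
    if n < 4:
        raise ValueError("need at least 4 samples")

    X = matrix.values.to_numpy(dtype=float)
    constant = np.ptp(X, axis=1) == 0
    excluded = matrix.feature_ids[constant].tolist()
    if excluded:
        logger.warning("%d constant feature(s) excluded from grade screening", len(excluded))

    Xr = stats.rankdata(X[~constant], axis=1)
    gr = stats.rankdata(g)
    Xc = Xr - Xr.mean(axis=1, keepdims=True)
    gc = gr - gr.mean()
    denom = np.sqrt((Xc * Xc).sum(axis=1) * (gc * gc).sum())
    rho = (Xc @ gc) / denom
    rho = np.clip(rho, -1.0, 1.0)

    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt((n - 2) / (1.0 - rho * rho))
    p_raw = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p_raw = np.where(np.abs(rho) >= 1.0, _TINY_P, p_raw)
    p_raw = np.clip(p_raw, _TINY_P, 1.0)

    assoc = pd.DataFrame(
        {
            "gene_symbol": matrix.gene_symbols()[~constant],
            "rho": rho,
            "p_raw": p_raw,
            "p_adj": bh_adjust(p_raw),
            "direction": np.sign(rho).astype(int),
        },
        index=matrix.feature_ids[~constant],
    )
    assoc.index.name = "feature_id"
    assoc.attrs["excluded_features"] = excluded
    logger.info(
        "grade screening: %d features tested, %d significant at BH 0.05",
        len(assoc), int((assoc["p_adj"] < 0.05).sum()),
    )
    return assoc


def build_signature(assoc: pd.DataFrame, restrict_to, alpha: float = 0.05) -> Signature:
    """Direction-weighted signature from genes in ``restrict_to`` passing ``alpha``.

    Screening is at feature (probe) level: a gene qualifies when at least one
    of its features has adjusted p < alpha; its weight is the shared sign of
    the qualifying features.  Genes whose qualifying features disagree in
    sign are excluded with a warning.
    """
    if not 0 <= alpha < 1:
        raise ValueError("alpha must lie in [0, 1)")
    restrict_to = set(restrict_to)
    if not restrict_to:
        raise ValueError("restrict_to gene set is empty")

    hits = assoc[
        assoc["gene_symbol"].isin(restrict_to)
        & (assoc["gene_symbol"] != "")
        & (assoc["p_adj"] < alpha)
        & (assoc["direction"] != 0)
    ]
    entries: list[tuple[str, int]] = []
    conflicted: list[str] = []
    for gene, sub in hits.groupby("gene_symbol", sort=True):
        signs = set(sub["direction"])
        if len(signs) > 1:
            conflicted.append(str(gene))
            continue
        entries.append((str(gene), int(signs.pop())))
    if conflicted:
        logger.warning("genes excluded for conflicting feature signs: %s", conflicted)
    if not entries:
        logger.warning("no qualifying genes at alpha=%g: empty signature", alpha)
    signature = Signature.from_entries(entries)
    logger.info(
        "signature: %d genes (%d up, %d down)",
        len(signature), len(signature.subset(1)), len(signature.subset(-1)),
    )
    return signature
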