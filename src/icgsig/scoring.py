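"""Standardized, direction-weighted risk score.

For a patient with log2 expression e_i of signature gene i, the risk score is

    S = sum_i W_i * (e_i - mu_i) / tau_i

where W_i is the gene's direction weight (+1/-1) and mu_i, tau_i are the
mean and standard deviation of gene i across all samples of the same cohort
(within-cohort standardization).  Patients with S > 0 are classed iCG+
(elevated predicted death risk); all others iCG-.  The zero cutoff is
scale-free, so any positive rescaling of S leaves the classes unchanged.
"""

from __future__ import annotations

import logging

import pandas as pd

from .containers import ExpressionMatrix, Signature

logger = logging.getLogger(__name__)

POSITIVE_CLASS = "iCG+"
NEGATIVE_CLASS = "iCG-"


class EmptySignatureError(ValueError):
    """No usable signature genes remain after exclusions."""


def standardize(matrix: ExpressionMatrix, genes) -> pd.DataFrame:
    """Per-gene mean (mu) and sample standard deviation (tau) across samples.

    Genes missing from the matrix, or with tau = 0, are dropped with a
    warning; the result covers the remaining genes only.
    """
    if matrix.n_samples < 2:
        raise ValueError("standardization needs at least 2 samples")
    genes = list(genes)
    present = [g for g in genes if g in matrix.values.index]
    absent = sorted(set(genes) - set(present))
    if absent:
        logger.warning("%d signature gene(s) absent from cohort: %s", len(absent), absent)
    sub = matrix.values.loc[present]
    mu = sub.mean(axis=1)
    tau = sub.std(axis=1, ddof=1)
    degenerate = tau.index[tau == 0].tolist()
    if degenerate:
        logger.warning("dropping constant gene(s) with tau=0: %s", degenerate)
    params = pd.DataFrame({"mu": mu, "tau": tau})[tau > 0]
    params.index.name = "gene_symbol"
    return params


def risk_score(
    matrix: ExpressionMatrix,
    signature: Signature,
    params: pd.DataFrame | None = None,
    cutoff: float = 0.0,
) -> pd.DataFrame:
    """Per-sample risk score S and iCG class.

    ``params`` defaults to within-cohort standardization of ``matrix``; pass
    explicit parameters only when they were derived from the same cohort.
    Returns a DataFrame indexed by sample id with columns ``score`` and
    ``icg_class`` (iCG+ iff S > cutoff; an exact-cutoff score is iCG-).
    """
    if params is None:
        params = standardize(matrix, signature.genes)
    usable = [g for g in signature.genes if g in params.index and g in matrix.values.index]
    if not usable:
        raise EmptySignatureError("no signature genes usable for scoring")
    if len(usable) < len(signature):
        logger.warning(
            "scoring with %d of %d signature genes", len(usable), len(signature)
        )
    expr = matrix.values.loc[usable]
    mu = params.loc[usable, "mu"]
    tau = params.loc[usable, "tau"]
    w = signature.weights.loc[usable]
    z = expr.sub(mu, axis=0).div(tau, axis=0)
    scores = z.mul(w, axis=0).sum(axis=0)
    profile = pd.DataFrame(
        {
            "score": scores,
            "icg_class": [POSITIVE_CLASS if s > cutoff else NEGATIVE_CLASS for s in scores],
        },
        index=matrix.sample_ids,
    )
    profile.index.name = "sample_id"
    return profile


def subset_signature(signature: Signature, direction: int) -> Signature:
    """Signature entries whose weight equals ``direction`` (+1 or -1)."""
    return signature.subset(direction)
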