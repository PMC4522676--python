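"""Random-signature significance testing (Venet-style resampling null).

A signature's prognostic strength is summarized by the Wald statistic Z of a
univariate Cox regression of survival on the dichotomized risk class.  To
ask whether the signature beats chance, B random signatures of the same size
are drawn from a gene pool; each is scored, dichotomized at zero, and fit
the same way, yielding an empirical null of Z values.  The right-tailed
empirical p is the fraction of null Z values at or above the observed Z.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import scoring
from .containers import ExpressionMatrix, Signature
from .survival import CoxError, univariate_wald_z

logger = logging.getLogger(__name__)


@dataclass
class GenePool:
    """Genes eligible for random-signature draws.

    ``directions`` optionally maps gene → ±1 (sign of its grade correlation
    in a discovery cohort); when present, sampled genes carry that sign as
    their weight, mirroring how the tested signature was built.  Without it
    every sampled gene gets weight +1.
    """

    genes: list[str]
    directions: pd.Series | None = None

    def __post_init__(self) -> None:
        self.genes = list(self.genes)
        if not self.genes:
            raise ValueError("gene pool is empty")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("gene pool contains duplicates")
        if self.directions is not None:
            self.directions = pd.Series(self.directions)

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class ResamplingResult:
    z_observed: float
    z_null: np.ndarray
    B: int
    n_failures: int = 0

    @property
    def p_empirical(self) -> float:
        return float(np.mean(self.z_null >= self.z_observed))

    def format_p(self) -> str:
        """Printed p: 'r/B' as a decimal, or '< 1/B' when no exceedances."""
        r = int((self.z_null >= self.z_observed).sum())
        if r == 0:
            return f"< {1.0 / self.B:g}"
        return f"{r / self.B:g}"

    def to_dict(self) -> dict:
        return {
            "z_observed": self.z_observed,
            "p_empirical": self.p_empirical,
            "p_display": self.format_p(),
            "B": self.B,
            "n_failures": self.n_failures,
        }


def draw_random_signature(pool: GenePool, size: int, rng: np.random.Generator) -> Signature:
    """Uniform sample of ``size`` genes without replacement from the pool."""
    if size > len(pool):
        raise ValueError(f"requested {size} genes from a pool of {len(pool)}")
    genes = rng.choice(pool.genes, size=size, replace=False)
    if pool.directions is not None:
        weights = [
            int(w) if (w := np.sign(pool.directions.get(g, 1))) != 0 else 1
            for g in genes
        ]
    else:
        weights = [1] * size
    return Signature.from_entries(zip(genes, weights))


def signature_wald_z(
    matrix: ExpressionMatrix, clinical: pd.DataFrame, signature: Signature
) -> float:
    """Wald Z of the univariate Cox fit on the signature's risk class.

    Raises CoxError when all patients land in one class or the fit fails.
    """
    profile = scoring.risk_score(matrix, signature)
    x = (profile.loc[matrix.sample_ids, "icg_class"] == scoring.POSITIVE_CLASS).to_numpy(float)
    time = clinical.loc[matrix.sample_ids, "time_months"].to_numpy(float)
    event = clinical.loc[matrix.sample_ids, "event"].to_numpy(float)
    return univariate_wald_z(x, time, event)


def resampling_test(
    matrix: ExpressionMatrix,
    clinical: pd.DataFrame,
    signature: Signature,
    pool: GenePool,
    B: int = 1000,
    rng: np.random.Generator | int | None = None,
) -> ResamplingResult:
    """Empirical right-tailed test of the signature's Z against random draws.

    Each of the B random signatures is scored on ``matrix`` (within-cohort
    standardization), dichotomized at zero, and fit by univariate Cox; its
    Wald Z enters the null.  Draws whose Cox fit fails (single class,
    separation) contribute Z = 0 — conservative toward significance of the
    observed signature — and are counted in ``n_failures``.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    rng = np.random.default_rng(rng)
    missing = matrix.sample_ids.difference(clinical.index)
    if len(missing):
        raise ValueError(f"clinical data missing for {len(missing)} sample(s)")

    z_observed = signature_wald_z(matrix, clinical, signature)
    z_null = np.zeros(B)
    failures = 0
    size = len(signature)
    for b in range(B):
        random_sig = draw_random_signature(pool, size, rng)
        try:
            z_null[b] = signature_wald_z(matrix, clinical, random_sig)
        except (CoxError, scoring.EmptySignatureError):
            z_null[b] = 0.0
            failures += 1
    if failures:
        logger.warning("%d of %d null Cox fits failed (recorded as Z=0)", failures, B)
    result = ResamplingResult(z_observed=z_observed, z_null=z_null, B=B, n_failures=failures)
    logger.info(
        "resampling test: z_observed=%.3f, empirical p %s (B=%d)",
        z_observed, result.format_p(), B,
    )
    return result
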