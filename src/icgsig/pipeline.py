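"""End-to-end orchestration: discovery → scoring → survival → resampling.

``run_full_analysis`` consumes a :class:`RunConfig` (file paths or a
synthetic cohort spec plus thresholds), writes every stage's table to an
output directory, and returns a machine-readable summary.  All randomness is
driven by the single configured seed; re-running with the same config yields
byte-identical outputs (timestamps live only in the run log).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, discovery, io, scoring, survival
from .containers import ExpressionMatrix, Signature
from .resampling import GenePool, resampling_test
from .synthetic import CohortSpec, generate_discovery_cohort, generate_validation_cohort

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Paths, thresholds, and optional synthetic-cohort settings for a run.

    With ``synthetic=True`` the discovery and validation cohorts are
    generated from ``cohort_spec`` (seeded from ``seed``) instead of read
    from files, and the generated inputs are written alongside the outputs.
    """

    discovery_expression: str | None = None
    discovery_clinical: str | None = None
    annotation: str | None = None
    calls: str | None = None
    validation_expression: str | None = None
    validation_clinical: str | None = None
    signature: str | None = None
    pool: str | None = None
    covariates: list[str] = field(default_factory=list)
    alpha: float = 0.05
    presence_fraction: float = 2.0 / 3.0
    B: int = 1000
    seed: int = 0
    cutoff: float = 0.0
    synthetic: bool = False
    cohort_spec: CohortSpec | None = None

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if not 0 < self.presence_fraction <= 1:
            raise ValueError("presence_fraction must lie in (0, 1]")
        if self.B < 1:
            raise ValueError("B must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        spec_raw = raw.pop("cohort_spec", None)
        cfg = cls(**raw)
        if spec_raw:
            cfg.cohort_spec = CohortSpec(**spec_raw)
        return cfg

    def config_hash(self) -> str:
        payload = dataclasses.asdict(self)
        if payload.get("cohort_spec") and isinstance(payload["cohort_spec"].get("planted"), dict):
            pass
        if self.cohort_spec is not None:
            payload["cohort_spec"] = {
                k: (list(v.planted) if k == "planted" else v)
                for k, v in dataclasses.asdict(self.cohort_spec).items()
                if k != "planted"
            }
            payload["cohort_spec"]["planted"] = dict(self.cohort_spec.planted.weights)
        text = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(text.encode()).hexdigest()[:12]


def _provenance(config: RunConfig) -> str:
    return f"icgsig v{__version__} config_hash={config.config_hash()} seed={config.seed}"


def _gene_directions(assoc: pd.DataFrame) -> pd.Series:
    """Per-gene direction: sign of the most significant feature's rho."""
    tested = assoc[(assoc["gene_symbol"] != "") & (assoc["direction"] != 0)]
    best = tested.sort_values("p_adj").drop_duplicates("gene_symbol")
    return pd.Series(best["direction"].to_numpy(), index=best["gene_symbol"].to_numpy())


def run_full_analysis(config: RunConfig, out_dir: str | Path) -> dict:
    """Run every pipeline stage and write the report bundle to ``out_dir``.

    Returns the summary dict (also written as ``summary.json``).  Stage
    failures raise with the stage named; an empty discovered signature is
    not a failure — downstream stages are skipped and recorded as such.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tag = _provenance(config)
    _setup_run_log(out / "run.log")
    logger.info("run start: %s", tag)
    logger.info(
        "thresholds: alpha=%g presence_fraction=%g B=%d cutoff=%g seed=%d",
        config.alpha, config.presence_fraction, config.B, config.cutoff, config.seed,
    )

    summary: dict = {
        "_meta": {"package": "icgsig", "version": __version__,
                  "config_hash": config.config_hash(), "seed": config.seed},
        "thresholds": {"alpha": config.alpha, "presence_fraction": config.presence_fraction,
                       "B": config.B, "cutoff": config.cutoff},
    }

    # ---- stage: inputs -----------------------------------------------------
    try:
        inputs = _load_inputs(config, out, tag)
    except Exception as exc:
        raise RuntimeError(f"[inputs] {exc}") from exc
    disc_matrix, grades, calls, val_matrix, val_clinical, fixed_signature = inputs

    # ---- stage: discovery --------------------------------------------------
    signature = fixed_signature
    if signature is None:
        try:
            signature, assoc, disc_stats = _run_discovery(
                config, disc_matrix, grades, calls, out, tag
            )
        except Exception as exc:
            raise RuntimeError(f"[discovery] {exc}") from exc
        summary["discovery"] = disc_stats
    else:
        assoc = None
        logger.info("using supplied signature (%d genes); discovery skipped", len(signature))
    summary["signature"] = {
        "size": len(signature),
        "n_up": len(signature.subset(1)) if len(signature) else 0,
        "n_down": len(signature.subset(-1)) if len(signature) else 0,
        "genes": {g: int(w) for g, w in signature},
    }
    if len(signature) == 0:
        logger.warning("empty signature: validation and resampling skipped")
        summary["skipped"] = ["scoring", "survival", "resampling"]
        _write_summary(summary, out)
        return summary

    # ---- stage: scoring + survival ----------------------------------------
    try:
        summary["validation"] = _run_validation(
            config, val_matrix, val_clinical, signature, out, tag
        )
    except Exception as exc:
        raise RuntimeError(f"[survival] {exc}") from exc

    # ---- stage: resampling -------------------------------------------------
    try:
        summary["resampling"] = _run_resampling(
            config, val_matrix, val_clinical, signature, assoc, out, tag
        )
    except Exception as exc:
        raise RuntimeError(f"[resampling] {exc}") from exc

    _write_summary(summary, out)
    logger.info("run complete: %s", tag)
    return summary


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _setup_run_log(path: Path) -> None:
    root = logging.getLogger("icgsig")
    for h in list(root.handlers):
        if getattr(h, "_icgsig_run_log", False):
            root.removeHandler(h)
    handler = logging.FileHandler(path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    handler._icgsig_run_log = True  # type: ignore[attr-defined]
    root.addHandler(handler)
    if root.level > logging.INFO or root.level == logging.NOTSET:
        root.setLevel(logging.INFO)


def _load_inputs(config: RunConfig, out: Path, tag: str):
    fixed_signature = io.read_signature(config.signature) if config.signature else None
    if config.synthetic:
        spec = config.cohort_spec or CohortSpec()
        disc_spec = spec.with_(seed=config.seed)
        val_spec = spec.with_(seed=config.seed + 1)
        disc_matrix, grades, calls = generate_discovery_cohort(disc_spec)
        val_matrix, val_clinical = generate_validation_cohort(val_spec)
        inputs_dir = out / "inputs"
        inputs_dir.mkdir(exist_ok=True)
        io.write_expression(disc_matrix, inputs_dir / "discovery_expression.tsv", tag)
        io.write_expression(val_matrix, inputs_dir / "validation_expression.tsv", tag)
        io.write_call_matrix(calls, inputs_dir / "discovery_calls.tsv")
        clin = val_clinical.copy()
        clin.index.name = "sample_id"
        clin.to_csv(inputs_dir / "validation_clinical.csv")
        disc_clin = pd.DataFrame({"grade": grades})
        disc_clin.index.name = "sample_id"
        disc_clin.to_csv(inputs_dir / "discovery_clinical.csv")
        return disc_matrix, grades, calls, val_matrix, val_clinical, fixed_signature

    if fixed_signature is not None and config.discovery_expression is None:
        disc_matrix = grades = calls = None
    else:
        if not (config.discovery_expression and config.discovery_clinical):
            raise ValueError("discovery expression and clinical paths are required")
        disc_matrix = io.read_expression(config.discovery_expression)
        if config.annotation:
            ann = io.read_annotation(config.annotation)
            disc_matrix = ExpressionMatrix(disc_matrix.values, ann)
        disc_clin = pd.read_csv(config.discovery_clinical, comment="#").set_index("sample_id")
        if "grade" not in disc_clin.columns:
            raise ValueError("discovery clinical table needs a 'grade' column")
        grades = disc_clin["grade"].astype(int)
        calls = io.read_call_matrix(config.calls) if config.calls else None

    if not (config.validation_expression and config.validation_clinical):
        raise ValueError("validation expression and clinical paths are required")
    val_matrix = io.read_expression(config.validation_expression)
    val_clinical = io.read_clinical(config.validation_clinical)
    return disc_matrix, grades, calls, val_matrix, val_clinical, fixed_signature


def _run_discovery(config, matrix, grades, calls, out: Path, tag: str):
    n_initial = matrix.n_features
    if calls is not None:
        kept = discovery.filter_by_presence(calls, config.presence_fraction)
        matrix = matrix.subset_features(matrix.feature_ids.intersection(kept))
    n_present = matrix.n_features
    matrix = discovery.filter_sex_chromosomes(matrix)
    n_retained = matrix.n_features

    assoc = discovery.correlate_with_grade(matrix, grades)
    io.write_association_table(assoc, out / "grade_association.tsv", tag)

    ion_genes = matrix.ion_channel_genes()
    stats: dict = {
        "features_initial": n_initial,
        "features_after_presence_filter": n_present,
        "features_after_sex_filter": n_retained,
        "features_tested": int(len(assoc)),
        "features_significant": int((assoc["p_adj"] < config.alpha).sum()),
    }
    if ion_genes:
        signature = discovery.build_signature(assoc, ion_genes, config.alpha)
        is_ion = assoc["gene_symbol"].isin(ion_genes)
        sig_down = (assoc["p_adj"] < config.alpha) & (assoc["direction"] == -1)
        stats["enrichment_p_down_ion"] = discovery.enrichment_test(
            int((sig_down & is_ion).sum()), int(sig_down.sum()),
            int(is_ion.sum()), len(assoc),
        )
        if is_ion.sum() >= 2 and (~is_ion).sum() >= 2:
            t, p = discovery.compare_rho_distributions(
                assoc.loc[is_ion, "rho"], assoc.loc[~is_ion, "rho"]
            )
            stats["rho_shift_t"] = t
            stats["rho_shift_p"] = p
    else:
        logger.warning("no ion-channel annotation: signature built over all genes")
        signature = discovery.build_signature(
            assoc, set(assoc["gene_symbol"]) - {""}, config.alpha
        )
    io.write_signature(signature, out / "signature.tsv", tag)
    return signature, assoc, stats


def _run_validation(config, matrix, clinical, signature, out: Path, tag: str) -> dict:
    profile = scoring.risk_score(matrix, signature, cutoff=config.cutoff)
    with open(out / "risk_profile.tsv", "w") as fh:
        fh.write(f"# {tag}\n")
        profile.to_csv(fh, sep="\t")

    merged = clinical.join(profile)
    merged["icg"] = (merged["icg_class"] == scoring.POSITIVE_CLASS).astype(int)

    time = merged["time_months"].to_numpy()
    event = merged["event"].to_numpy()
    group = merged["icg_class"].to_numpy()
    results: dict = {
        "n": int(len(merged)),
        "n_icg_pos": int(merged["icg"].sum()),
        "n_events": int(event.sum()),
    }

    curves = survival.km_estimate(time, event, group)
    km_rows = []
    for label, s in curves.items():
        for t, v in s.items():
            km_rows.append((label, t, v))
    km = pd.DataFrame(km_rows, columns=["icg_class", "time", "survival"])
    with open(out / "km_curves.tsv", "w") as fh:
        fh.write(f"# {tag}\n")
        km.to_csv(fh, sep="\t", index=False)

    if merged["icg"].nunique() == 2:
        chi2, p = survival.logrank_test(time, event, group)
        results["logrank_chi2"] = chi2
        results["logrank_p"] = p
        uni = survival.cox_fit(merged, ["icg"])
        with open(out / "cox_univariate.tsv", "w") as fh:
            fh.write(f"# {tag}\n")
            uni.to_csv(fh, sep="\t")
        results["cox_univariate"] = uni.loc["icg"].to_dict()
        covs = [c for c in config.covariates if c in merged.columns]
        if covs:
            multi = survival.cox_fit(merged, ["icg"] + covs)
            with open(out / "cox_multivariate.tsv", "w") as fh:
                fh.write(f"# {tag}\n")
                multi.to_csv(fh, sep="\t")
            results["cox_multivariate"] = {
                c: multi.loc[c].to_dict() for c in multi.index
            }
    else:
        logger.warning("all patients in one risk class: survival tests skipped")
        results["skipped"] = "single risk class"
    return results


def _run_resampling(config, matrix, clinical, signature, assoc, out: Path, tag: str) -> dict:
    if config.pool:
        pool_genes = io.read_gene_list(config.pool)
    else:
        pool_genes = [g for g in matrix.values.index]
    directions = _gene_directions(assoc) if assoc is not None else None
    pool = GenePool(pool_genes, directions)
    rng = np.random.default_rng(config.seed)
    result = resampling_test(matrix, clinical, signature, pool, B=config.B, rng=rng)

    null_df = pd.DataFrame({"z_null": result.z_null})
    with open(out / "null_z.tsv", "w") as fh:
        fh.write(f"# {tag}\n")
        null_df.to_csv(fh, sep="\t", index=False)
    payload = result.to_dict()
    payload["_meta"] = {"config_hash": config.config_hash(), "seed": config.seed}
    with open(out / "resampling.json", "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
    return result.to_dict()


def _write_summary(summary: dict, out: Path) -> None:
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=float)
        fh.write("\n")
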