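"""End-to-end study orchestration.

``run_pipeline`` executes the two-stage analysis: (1) build the typology of
violence situations by consensus-resampled PAM on Gower dissimilarities, and
(2) evaluate scale behaviour against it — descriptives, between-physician
comparisons, TIW regressions, and profile-matched inter-/intra-rater
concordance, with an optional fine-profile sensitivity rerun.

Every stage draws its seed from one master seed through named
``numpy.random.SeedSequence`` children, so a run is reproducible end to end
and the manifest records enough to replay it.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort import Cohort, SCALE_COLUMNS, SYMPTOM_CONCEPTS
from .concordance import concordance_analysis, labels_series, sensitivity_fine_profiles
from .config import GeneratorConfig, default_config
from .consensus import assign_profiles, consensus_clustering
from .gower import gower_dissimilarity
from .mining import Lexicon, default_lexicon, extract_features
from .scale_stats import describe_by_profile, ols_univariate, physician_rating_comparison
from .simulate import apply_missingness, generate_cohort, render_certificates

__all__ = ["apply_eligibility", "run_pipeline", "write_report", "PipelineSettings"]

logger = logging.getLogger(__name__)

#: Stage names, in execution order; each gets its own derived seed.
STAGES = ("simulate", "certificates", "missingness", "cluster", "concordance", "sensitivity")

_DELAY_LIMIT_HOURS = 720.0  # 30 days; records at exactly 720 h are retained
_MIN_AGE_YEARS = 10.0
_MIN_ANNUAL_CASELOAD = 300


def stage_seeds(master_seed: int) -> dict[str, int]:
    """Derive one sub-seed per pipeline stage from the master seed."""
    children = np.random.SeedSequence(master_seed).spawn(len(STAGES))
    return {
        name: int(child.generate_state(1)[0] % (2**31))
        for name, child in zip(STAGES, children)
    }


def apply_eligibility(
    cohort: Cohort,
    completeness_scope: str = "scales_tiw_features",
) -> tuple[Cohort, dict[str, int]]:
    """Apply the study eligibility filter and log exclusions per rule.

    Rules, applied in order (a record is logged under the first rule it
    trips): age below 10 years; unintentional violence or neglect;
    consultation more than 30 days (720 h) after the incident; physicians
    with fewer than 300 patients in the cohort year; second evaluations;
    incomplete records.  ``completeness_scope`` controls the last rule:
    ``"scales_tiw"`` requires the nine scales and TIW, the default
    ``"scales_tiw_features"`` additionally requires the clustering features.
    """
    df = cohort.df
    required = ["age", "intentional", "delay_hours", "physician_id", "second_evaluation",
                "tiw_days"] + SCALE_COLUMNS
    for col in required:
        if col not in df.columns:
            raise ValueError(f"eligibility filter requires column {col!r}")

    # caseloads are evaluated on the loaded cohort (one study year assumed)
    caseload = df["physician_id"].value_counts()
    small_physicians = set(caseload[caseload < _MIN_ANNUAL_CASELOAD].index)

    complete_cols = SCALE_COLUMNS + ["tiw_days"]
    if completeness_scope == "scales_tiw_features":
        complete_cols = complete_cols + list(cohort.feature_spec)
    elif completeness_scope != "scales_tiw":
        raise ValueError(f"unknown completeness_scope {completeness_scope!r}")

    rules = [
        ("age_below_10", df["age"] < _MIN_AGE_YEARS),
        ("unintentional", df["intentional"].astype(bool) == False),  # noqa: E712
        ("delay_over_30_days", df["delay_hours"] > _DELAY_LIMIT_HOURS),
        ("physician_caseload_below_300", df["physician_id"].isin(small_physicians)),
        ("second_evaluation", df["second_evaluation"].astype(bool)),
        ("incomplete_data", df[complete_cols].isna().any(axis=1)),
    ]
    excluded = np.zeros(len(df), dtype=bool)
    log: dict[str, int] = {}
    for name, mask in rules:
        mask = mask.to_numpy(dtype=bool)
        newly = mask & ~excluded
        log[name] = int(newly.sum())
        excluded |= newly
    kept = df[~excluded].reset_index(drop=True)
    log["total_excluded"] = int(excluded.sum())
    log["n_input"] = len(df)
    log["n_retained"] = len(kept)
    return Cohort(kept, dict(cohort.feature_spec)), log


@dataclass
class PipelineSettings:
    """Desk-scale defaults for a full run; every stage can be toggled."""

    generator: GeneratorConfig | None = None  # default_config() when None
    input_csv: str | None = None              # load instead of simulating
    mine_certificates: bool = True
    lexicon: Lexicon | None = None
    k_range: tuple = tuple(range(2, 11))
    n_resamples: int = 50
    subsample_frac: float = 0.8
    concordance_scales: list[str] = field(default_factory=lambda: ["pain_assault"])
    repetitions: int = 100
    run_sensitivity: bool = True
    sensitivity_repetitions: int = 20
    n_profiles_large: int | None = None  # default n // 5
    completeness_scope: str = "scales_tiw_features"


def run_pipeline(
    settings: PipelineSettings | None = None,
    master_seed: int = 0,
    out_dir: str | Path | None = None,
    force: bool = False,
) -> dict:
    """Execute simulate/load -> mine -> eligibility -> typology -> statistics
    -> concordance -> sensitivity, returning all stage outputs.

    When ``out_dir`` is given the outputs are also written as a report
    bundle (see :func:`write_report`).
    """
    settings = settings or PipelineSettings()
    seeds = stage_seeds(master_seed)
    outputs: dict = {"seeds": seeds, "master_seed": master_seed}

    # -- acquire the cohort ------------------------------------------------
    if settings.input_csv is not None:
        cohort = Cohort.from_csv(settings.input_csv)
        logger.info("loaded %d records from %s", len(cohort), settings.input_csv)
    else:
        gen_cfg = settings.generator or default_config()
        gen_cfg = gen_cfg.with_overrides(seed=seeds["simulate"])
        cohort = generate_cohort(gen_cfg)
        if settings.mine_certificates:
            lexicon = settings.lexicon or default_lexicon()
            cohort = render_certificates(cohort, lexicon, gen_cfg.typo_rate,
                                         seeds["certificates"])
        if gen_cfg.missing_rate > 0:
            cohort = apply_missingness(cohort, gen_cfg.missing_rate, seeds["missingness"])
        outputs["generator_config"] = gen_cfg.to_dict()
        logger.info("simulated %d records", len(cohort))

    # -- certificate mining ------------------------------------------------
    has_text = (
        "certificate_text" in cohort.df.columns
        and cohort.df["certificate_text"].notna().any()
    )
    if settings.mine_certificates and has_text:
        lexicon = settings.lexicon or default_lexicon()
        mined = []
        for text in cohort.df["certificate_text"].fillna(""):
            mined.append(extract_features(str(text), lexicon).flags)
        flags = pd.DataFrame(mined, index=cohort.df.index)
        for concept in SYMPTOM_CONCEPTS:
            if concept in flags.columns:
                cohort.df[f"symptom_{concept}"] = flags[concept].astype(int)
        outputs["mining"] = {"n_mined": len(flags)}
    else:
        outputs["mining"] = {"skipped": True}

    # -- eligibility -------------------------------------------------------
    cohort, exclusion_log = apply_eligibility(cohort, settings.completeness_scope)
    outputs["eligibility"] = exclusion_log
    outputs["cohort"] = cohort

    # -- typology ----------------------------------------------------------
    dissim = gower_dissimilarity(cohort)
    consensus = consensus_clustering(
        dissim,
        k_range=settings.k_range,
        n_resamples=settings.n_resamples,
        subsample_frac=settings.subsample_frac,
        seed=seeds["cluster"],
    )
    clustering, summary = assign_profiles(cohort, dissim, consensus.selected_k)
    labels = labels_series(clustering)
    outputs["consensus"] = consensus
    outputs["clustering"] = clustering
    outputs["profile_summary"] = summary

    # -- scale statistics --------------------------------------------------
    lab_array = labels.reindex(cohort.df["patient_id"]).to_numpy()
    outputs["scales_by_profile"] = describe_by_profile(cohort, lab_array)
    regressions = []
    for scale in SCALE_COLUMNS:
        try:
            res = ols_univariate(cohort, scale)
            regressions.append(vars(res))
        except ValueError as exc:
            regressions.append({"scale": scale, "error": str(exc)})
    outputs["tiw_regressions"] = pd.DataFrame(regressions)
    outputs["physician_comparison"] = {
        scale: physician_rating_comparison(cohort, lab_array, scale)
        for scale in settings.concordance_scales
    }

    # -- concordance -------------------------------------------------------
    physicians = sorted(cohort.df["physician_id"].dropna().unique().tolist())
    inter_contexts = list(combinations(physicians, 2))
    concordance_rows = []
    for scale in settings.concordance_scales:
        inter = concordance_analysis(cohort, labels, scale, inter_contexts,
                                     settings.repetitions, seeds["concordance"])
        intra = concordance_analysis(cohort, labels, scale, physicians,
                                     settings.repetitions, seeds["concordance"])
        for kind, results in (("interrater", inter), ("intrarater", intra)):
            for ctx, res in results.items():
                concordance_rows.append(
                    {
                        "scale": scale,
                        "kind": kind,
                        "context": str(ctx),
                        "W_mean": res.W_mean,
                        "W_p2_5": res.W_p2_5,
                        "W_p97_5": res.W_p97_5,
                        "repetitions": res.repetitions,
                        "n_undefined": res.n_undefined,
                    }
                )
    outputs["concordance"] = pd.DataFrame(concordance_rows)

    # -- sensitivity -------------------------------------------------------
    if settings.run_sensitivity:
        sens = sensitivity_fine_profiles(
            cohort,
            dissim,
            labels,
            settings.concordance_scales[0],
            inter_contexts,
            repetitions=settings.sensitivity_repetitions,
            seed=seeds["sensitivity"],
            n_profiles_large=settings.n_profiles_large,
        )
        outputs["sensitivity"] = sens
    else:
        outputs["sensitivity"] = None

    if out_dir is not None:
        outputs["manifest"] = write_report(outputs, out_dir, force=force)
    return outputs


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_report(outputs: dict, out_dir: str | Path, force: bool = False) -> dict:
    """Write the report bundle: CSV/JSON artifacts, manifest and summary.

    Refuses a nonempty destination directory unless ``force`` is set.
    Returns the manifest (also written as ``manifest.json``) whose digests
    are SHA-256 hashes of every written artifact.
    """
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not force:
        raise FileExistsError(f"output directory {out} is not empty (use force)")
    out.mkdir(parents=True, exist_ok=True)

    written: list[Path] = []

    def _write_df(name: str, df: pd.DataFrame) -> None:
        path = out / name
        df.to_csv(path, index=False)
        written.append(path)

    def _write_json(name: str, obj) -> None:
        path = out / name
        path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=str),
                        encoding="utf-8")
        written.append(path)

    summary_lines = [f"vioscales pipeline report (package {__version__})"]

    cohort = outputs.get("cohort")
    if cohort is not None:
        cohort.to_csv(out / "cohort.csv")
        written.append(out / "cohort.csv")
        summary_lines.append(f"cohort: {len(cohort)} eligible records")
    if "eligibility" in outputs:
        _write_json("exclusion_log.json", outputs["eligibility"])
    if outputs.get("generator_config"):
        _write_json("generator_config.json", outputs["generator_config"])

    consensus = outputs.get("consensus")
    if consensus is not None:
        _write_df("consensus_metrics.csv", consensus.metrics.reset_index())
        _write_json("consensus_selection.json", {"selected_k": consensus.selected_k})
        summary_lines.append(f"selected number of profiles: {consensus.selected_k}")
    clustering = outputs.get("clustering")
    if clustering is not None:
        _write_df(
            "labels.csv",
            pd.DataFrame({"patient_id": clustering.ids, "profile": clustering.labels}),
        )
    if outputs.get("profile_summary") is not None:
        _write_df("profile_summary.csv", outputs["profile_summary"])
    if outputs.get("scales_by_profile") is not None:
        _write_df("scales_by_profile.csv", outputs["scales_by_profile"])
    if outputs.get("tiw_regressions") is not None:
        _write_df("tiw_regressions.csv", outputs["tiw_regressions"])
        betas = outputs["tiw_regressions"]
        if "beta" in betas.columns:
            ok = betas.dropna(subset=["beta"]) if "beta" in betas else betas
            summary_lines.append(
                "TIW regression betas: "
                + ", ".join(f"{r.scale}={r.beta:.2f}" for r in ok.itertuples())
            )
    if outputs.get("physician_comparison"):
        comp_summary = {}
        for scale, comp in outputs["physician_comparison"].items():
            comp_summary[scale] = {
                "overall_significant_pairs": comp["overall"]["n_significant_pairs"],
                "overall_pairs": comp["overall"]["n_pairs"],
                "within_profile_significant_pairs": {
                    str(pr): res["n_significant_pairs"]
                    for pr, res in comp["per_profile"].items()
                },
            }
        _write_json("physician_comparison.json", comp_summary)
        for scale, s in comp_summary.items():
            summary_lines.append(
                f"{scale}: {s['overall_significant_pairs']}/{s['overall_pairs']} "
                "significant physician pairs overall"
            )
    conc = outputs.get("concordance")
    if conc is not None and len(conc):
        _write_df("concordance.csv", conc)
        defined = conc.dropna(subset=["W_mean"])
        if len(defined):
            summary_lines.append(
                f"pooled Kendall W range: {defined['W_mean'].min():.2f}"
                f"-{defined['W_mean'].max():.2f}"
            )
    sens = outputs.get("sensitivity")
    if sens is None:
        summary_lines.append("sensitivity: skipped")
    elif len(sens):
        _write_df("sensitivity.csv", sens)
        summary_lines.append(
            f"fine-profile sensitivity: mean delta W = {sens['delta'].mean():+.3f}"
        )

    (out / "summary.txt").write_text("\n".join(summary_lines) + "\n", encoding="utf-8")
    written.append(out / "summary.txt")

    manifest = {
        "package_version": __version__,
        "master_seed": outputs.get("master_seed"),
        "stage_seeds": outputs.get("seeds"),
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "digests": {p.name: _sha256(p) for p in sorted(written)},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2), encoding="utf-8")
    return manifest
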