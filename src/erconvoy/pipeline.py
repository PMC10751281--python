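"""End-to-end orchestration: read -> bursts -> eligibility -> convoys ->
group statistics -> effectiveness models, with full provenance."""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import pandas as pd

from . import __version__
from .codebook import Codebook, default_codebook, load_codebook
from .esm_io import (
    DEFAULT_GAP_DAYS,
    DEFAULT_MIN_INSTANCES,
    StudyDataset,
    assign_bursts,
    filter_eligible,
    read_esm_csv,
)
from .convoy import build_convoys
from .group_stats import (
    factorial_anova,
    games_howell,
    person_level_summaries,
    shares_with_age,
)
from .models import build_model_frame, fit_model_sequence

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All options of a pipeline run; serialized into run metadata."""

    esm_path: str
    participants_path: str
    codebook_path: str = "default"
    gap_days: float = DEFAULT_GAP_DAYS
    min_instances: int = DEFAULT_MIN_INSTANCES
    recompute_bursts: bool = True
    boundary_rule: str = "outer_wins"
    percentile_convention: str = "nearest_rank"
    ss_type: int = 1
    fit_models: bool = True
    select_slopes: bool = True
    seed: int = 0
    out_dir: str = "runs/out"


def _load_codebook(spec: str) -> Codebook:
    return default_codebook() if spec == "default" else load_codebook(spec)


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full pipeline and write all artifacts to the run directory.

    Raises on any stage failure (the error names the stage); deterministic
    given inputs and options.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}
    stage = "read"
    try:
        t0 = time.perf_counter()
        codebook = _load_codebook(config.codebook_path)
        dataset = read_esm_csv(config.esm_path, config.participants_path, codebook)
        log.info("read %d observations, %d participants", len(dataset.observations), len(dataset.participants))
        timings[stage] = time.perf_counter() - t0

        stage = "bursts"
        t0 = time.perf_counter()
        dataset = assign_bursts(dataset, config.gap_days, recompute=config.recompute_bursts)
        timings[stage] = time.perf_counter() - t0

        stage = "eligibility"
        t0 = time.perf_counter()
        dataset = filter_eligible(dataset, config.min_instances)
        log.info("%d participants eligible", dataset.participants["participant_id"].nunique())
        timings[stage] = time.perf_counter() - t0

        stage = "convoys"
        t0 = time.perf_counter()
        results = build_convoys(
            dataset,
            codebook,
            boundary_rule=config.boundary_rule,
            convention=config.percentile_convention,
        )
        log.info(
            "built %d convoys over %d participants (%.1f%% regulation instances)",
            len(results.convoys),
            len(results.cutoffs),
            100 * results.instance_proportion,
        )
        results.convoys_frame().to_csv(out / "convoys.csv", index=False)
        results.cutoffs_frame().to_csv(out / "cutoffs.csv", index=False)
        results.shares.to_csv(out / "shares.csv", index=False)
        coding_cols = ["participant_id", "timestamp", "burst"] + [
            c for c in results.codings.columns if c.startswith("top_")
        ]
        results.codings[coding_cols].to_csv(out / "instances_coded.csv", index=False)
        timings[stage] = time.perf_counter() - t0

        stage = "group_stats"
        t0 = time.perf_counter()
        instances = results.codings
        summaries = person_level_summaries(
            instances, dataset.participants, codebook, codings=results.codings
        )
        summaries.to_csv(out / "person_summaries.csv", index=False)
        shares_aged = shares_with_age(results.shares, dataset.participants)
        n_cells = shares_aged.groupby(
            ["age_group", "category", "circle", "burst"], observed=True
        ).ngroups
        if len(shares_aged) > n_cells:
            anova = factorial_anova(shares_aged, ss_type=config.ss_type)
            anova.to_csv(out / "anova.csv", index=False)
        else:
            log.warning(
                "factorial ANOVA skipped: no residual degrees of freedom "
                "(%d shares across %d design cells)", len(shares_aged), n_cells
            )
        inner = shares_aged[shares_aged["circle"] == "inner"]
        pw_rows = []
        for cat, sub in inner.groupby("category"):
            groups = {g: s["share"].to_numpy() for g, s in sub.groupby("age_group")}
            try:
                pw = games_howell(groups)
            except ValueError as exc:
                log.warning("pairwise comparisons skipped for %s: %s", cat, exc)
                continue
            pw.insert(0, "category", cat)
            pw_rows.append(pw)
        if pw_rows:
            pd.concat(pw_rows, ignore_index=True).to_csv(out / "pairwise.csv", index=False)
        timings[stage] = time.perf_counter() - t0

        models_summary = None
        if config.fit_models:
            stage = "effectiveness"
            t0 = time.perf_counter()
            frame = build_model_frame(results.codings, dataset.participants)
            sequence = fit_model_sequence(frame, select_slopes=config.select_slopes)
            models_summary = sequence.to_dict()
            (out / "models.json").write_text(json.dumps(models_summary, indent=2))
            (out / "models.txt").write_text(format_model_table(sequence))
            timings[stage] = time.perf_counter() - t0

        stage = "provenance"
        meta = {
            "config": asdict(config),
            "codebook_digest": codebook.digest(),
            "convoy_options": results.options,
            "package_version": __version__,
            "n_participants": int(dataset.participants["participant_id"].nunique()),
            "n_observations": int(len(dataset.observations)),
            "n_instances": int(len(results.codings)),
            "instance_proportion": results.instance_proportion,
            "timings_s": {k: round(v, 3) for k, v in timings.items()},
        }
        (out / "run_metadata.json").write_text(json.dumps(meta, indent=2))
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return out


def format_model_table(sequence) -> str:
    """Human-readable fixed-effect table across the model sequence."""
    fits = sequence.fits()
    names = ["model1", "model2", "model3", "final"]
    terms: list[str] = []
    for n in names:
        for t in fits[n].params.index:
            if t not in terms:
                terms.append(t)
    lines = []
    header = f"{'Predictor':<28}" + "".join(f"{n:>18}" for n in names)
    lines.append(header)
    lines.append("-" * len(header))
    for t in terms:
        row = f"{t:<28}"
        for n in names:
            fit = fits[n]
            if t in fit.params.index:
                stars = (
                    "***" if fit.pvalues[t] < 0.001
                    else "**" if fit.pvalues[t] < 0.01
                    else "*" if fit.pvalues[t] < 0.05
                    else ""
                )
                row += f"{fit.params[t]:>11.2f}{stars:<3} ({fit.bse[t]:.2f})"[:18].rjust(18)
            else:
                row += f"{'':>18}"
        lines.append(row)
    lines.append("-" * len(header))
    for label, attr in (
        ("Residual (L1)", "scale"),
        ("ICC", "icc"),
        ("AIC", "aic"),
        ("BIC", "bic"),
    ):
        row = f"{label:<28}"
        for n in names:
            row += f"{getattr(fits[n], attr):>18.3f}"
        lines.append(row)
    row = f"{'Marginal/Conditional R2':<28}"
    for n in names:
        f = fits[n]
        row += f"{f.r2_marginal:.3f}/{f.r2_conditional:.3f}".rjust(18)
    lines.append(row)
    return "\n".join(lines) + "\n"
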