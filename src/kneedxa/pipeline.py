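"""Run orchestration: directory-level grading and cohort-level validation.

``run_grade`` walks a directory of landmark point files (with optional
osteophyte masks or a per-site area table), applies the classifier to each
scan, and writes a deterministic per-scan CSV plus a manifest recording the
configuration hash, the inputs, and every scan that failed validation with
its reason. ``run_validate`` joins grades onto a covariate/outcome table and
fits the full crude/adjusted association grid.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd

from . import __version__
from .association import AssocResult, ModelError, fit_coxph, fit_logistic, sex_interaction
from .config import GraderConfig, config_hash
from .io import PtsParseError, read_area_table, read_mask, read_pts
from .scoring import grade_scan

logger = logging.getLogger(__name__)

DEFAULT_ADJUST = ("age", "sex", "height_cm", "weight_kg", "ethnicity")

_FLOAT_FMT = "%.6f"


@dataclass
class RunManifest:
    """Provenance record for one pipeline run."""

    tool_version: str
    config_sha256: str
    inputs: list[str] = field(default_factory=list)
    n_ok: int = 0
    failures: list[dict] = field(default_factory=list)

    def save(self, path: Union[str, Path]) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, sort_keys=True) + "\n")


def run_grade(
    input_dir: Union[str, Path],
    cfg: GraderConfig,
    out_csv: Union[str, Path],
    *,
    masks_dir: Optional[Union[str, Path]] = None,
    area_table: Optional[Union[str, Path]] = None,
    heights: Optional[pd.DataFrame] = None,
    mean_height_cm: Optional[float] = None,
) -> tuple[pd.DataFrame, RunManifest]:
    """Grade every ``*.pts`` scan in a directory.

    Osteophyte annotations are looked up per scan as ``<stem>.png`` in
    ``masks_dir`` (or next to the pts file), or from an ``area_table`` CSV
    keyed by subject id; a scan with neither gets four grade-0 sites. Scans
    failing validation are listed in the manifest, not silently dropped.
    Output is byte-deterministic for fixed inputs and config.
    """
    input_dir = Path(input_dir)
    pts_files = sorted(input_dir.glob("*.pts"))
    if not pts_files:
        raise FileNotFoundError(f"no .pts files in {input_dir}")

    areas_by_subject = read_area_table(area_table) if area_table else {}
    height_by_subject: dict[str, float] = {}
    if heights is not None:
        height_by_subject = dict(
            zip(heights["subject_id"].astype(str), heights["height_cm"].astype(float))
        )

    manifest = RunManifest(
        tool_version=__version__,
        config_sha256=config_hash(cfg),
        inputs=[p.name for p in pts_files],
    )
    rows = []
    for path in pts_files:
        try:
            lm = read_pts(path)
            mask_path = Path(masks_dir or input_dir) / f"{path.stem}.png"
            if mask_path.exists():
                annotations = read_mask(mask_path, cfg, lm.pixel_spacing_mm)
            else:
                annotations = areas_by_subject.get(lm.subject_id, [])
            h = height_by_subject.get(lm.subject_id)
            rec = grade_scan(
                lm, annotations, cfg,
                height_cm=h if mean_height_cm is not None else None,
                mean_height_cm=mean_height_cm if h is not None else None,
            )
            rows.append(rec.to_row())
        except (PtsParseError, ValueError) as exc:
            logger.warning("skipping %s: %s", path.name, exc)
            manifest.failures.append({"input": path.name, "reason": str(exc)})
    if not rows:
        raise RuntimeError(f"no valid scans in {input_dir}")
    manifest.n_ok = len(rows)

    df = pd.DataFrame(rows).sort_values("subject_id", kind="stable").reset_index(drop=True)
    df.to_csv(out_csv, index=False, float_format=_FLOAT_FMT)
    return df, manifest


_OUTCOMES = {
    "pain": ("logistic", None),
    "hes_koa": ("logistic", None),
    "tkr": ("cox", "tkr_time_years"),
}


def run_validate(
    grades: Union[pd.DataFrame, str, Path],
    cohort: Union[pd.DataFrame, str, Path],
    *,
    exposures: Sequence[str] = ("rkoa_grade_collapsed", "jsn_grade"),
    outcomes: Sequence[str] = ("pain", "hes_koa", "tkr"),
    adjust: Sequence[str] = DEFAULT_ADJUST,
    stratify_sex: bool = False,
    interaction: bool = False,
) -> pd.DataFrame:
    """Fit the crude/adjusted association grid and return it as a tidy table.

    ``grades`` may be a grading CSV (joined to the cohort on ``subject_id``)
    or a frame already holding the exposure columns; passing the cohort frame
    for both is allowed when it already contains the grades. Outcomes with no
    events are skipped with a logged notice rather than failing the grid.
    """
    gdf = pd.read_csv(grades, dtype={"subject_id": str}) if not isinstance(grades, pd.DataFrame) else grades
    cdf = pd.read_csv(cohort, dtype={"subject_id": str}) if not isinstance(cohort, pd.DataFrame) else cohort
    if gdf is cdf or set(gdf.columns) >= set(cdf.columns):
        df = cdf
    else:
        overlap = (set(gdf.columns) & set(cdf.columns)) - {"subject_id"}
        df = gdf.drop(columns=list(overlap)).merge(cdf, on="subject_id", how="inner")
        unmatched = len(cdf) - len(df)
        if unmatched:
            logger.warning("%d cohort rows had no matching grades", unmatched)
    if df.empty:
        raise RuntimeError("no rows after joining grades and cohort")

    results: list[AssocResult] = []
    strata = [("all", df)]
    if stratify_sex:
        strata += [(s, df[df["sex"] == s]) for s in ("female", "male")]

    for outcome in outcomes:
        kind, time_col = _OUTCOMES[outcome]
        if df[outcome].sum() == 0:
            logger.warning("outcome %s has zero events; stage skipped", outcome)
            continue
        for exposure in exposures:
            for adjusted, adj in ((False, ()), (True, tuple(adjust))):
                for name, sub in strata:
                    adj_s = tuple(a for a in adj if a != "sex") if name != "all" else adj
                    try:
                        if kind == "logistic":
                            res = fit_logistic(sub, outcome, exposure, adj_s, stratum=name)
                        else:
                            res = fit_coxph(sub, time_col, outcome, exposure, adj_s, stratum=name)
                    except ModelError as exc:
                        logger.warning(
                            "%s ~ %s (%s, %s) failed: %s",
                            outcome, exposure, "adj" if adjusted else "crude", name, exc,
                        )
                        continue
                    results.extend(res)
                if interaction:
                    try:
                        pint = sex_interaction(
                            df, outcome, exposure, adjust if adjusted else (),
                            time=time_col if kind == "cox" else None,
                        )
                    except ModelError as exc:
                        logger.warning("interaction for %s ~ %s failed: %s", outcome, exposure, exc)
                        pint = {}
                    for i, r in enumerate(results):
                        if (
                            r.outcome == outcome and r.exposure == exposure
                            and r.adjusted == adjusted and r.stratum == "all"
                            and r.level in pint
                        ):
                            results[i] = AssocResult(**{**asdict(r), "interaction_p": pint[r.level]})

    return pd.DataFrame([asdict(r) for r in results])


def format_report(assoc: pd.DataFrame) -> str:
    """Render an association table as a plain-text report."""
    if assoc.empty:
        return "no association results\n"
    lines = []
    for (outcome, measure), block in assoc.groupby(["outcome", "measure"], sort=True):
        lines.append(f"Outcome: {outcome} ({measure}, vs grade-0 reference)")
        for _, r in block.iterrows():
            tag = "adjusted" if r["adjusted"] else "crude"
            extra = f"  [{r['flag']}]" if isinstance(r.get("flag"), str) else ""
            pint = (
                f"  p_interaction(sex)={r['interaction_p']:.3f}"
                if pd.notna(r.get("interaction_p")) else ""
            )
            lines.append(
                f"  {r['exposure']}={r['level']} ({tag}, {r['stratum']}): "
                f"{measure} {r['estimate']:.2f} "
                f"(95% CI {r['ci_low']:.2f}, {r['ci_high']:.2f}), "
                f"p={r['p_value']:.2e}, events={r['n_events']}{pint}{extra}"
            )
        lines.append("")
    return "\n".join(lines) + "\n"
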