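"""File formats and the end-to-end pipeline.

Canonical specimen table: a comma-separated, UTF-8, headered CSV with
columns

    id, year, doy, latitude, longitude, elevation, spring_tmax, winter_ppt,
    manual_buds, manual_flowers, manual_immature, manual_mature,
    [pred_buds, pred_flowers, pred_immature, pred_mature]

The ``pred_*`` block is optional as a whole: a table scored only by humans
omits it.  ``counts_from_coco`` reduces a COCO-style instance-annotation
JSON (images / annotations / categories) to per-image per-class counts
through a user-supplied category-name map.  ``run_pipeline`` ties
simulation or ingestion, PI scoring, detector evaluation and model fitting
together into one reproducible artifact directory.
"""

from __future__ import annotations

import json
import logging
import tomllib
from dataclasses import asdict
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import evaluation, models
from .phenology import ORGAN_CLASSES, OrganCounts, SpecimenRecord, pi_table
from .simulate import SimulationConfig, simulate_collection

logger = logging.getLogger(__name__)

__all__ = ["read_specimens", "write_specimens", "counts_from_coco",
           "run_pipeline", "load_config"]

META_COLUMNS = ["id", "year", "doy", "latitude", "longitude", "elevation",
                "spring_tmax", "winter_ppt"]
MANUAL_COLUMNS = ["manual_buds", "manual_flowers", "manual_immature", "manual_mature"]
PRED_COLUMNS = ["pred_buds", "pred_flowers", "pred_immature", "pred_mature"]


class SchemaError(ValueError):
    """A specimen table is missing columns or contains invalid rows."""


def _parse_counts(row: pd.Series, cols: Sequence[str], rownum: int) -> OrganCounts:
    vals = []
    for c in cols:
        v = row[c]
        if pd.isna(v) or float(v) != int(v) or int(v) < 0:
            raise SchemaError(f"row {rownum}: column {c} must be a non-negative integer, got {v!r}")
        vals.append(int(v))
    return OrganCounts(*vals)


def read_specimens(path: str | Path, rename: Mapping[str, str] | None = None) -> list[SpecimenRecord]:
    """Read a canonical specimen CSV into records.

    ``rename`` maps columns of a foreign table onto the canonical names
    (``{"their_name": "canonical_name"}``) so externally produced tables
    need not be rewritten.  Validation failures name the offending row.
    """
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    if rename:
        df = df.rename(columns=dict(rename))
    missing = [c for c in META_COLUMNS + MANUAL_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    pred_present = [c for c in PRED_COLUMNS if c in df.columns]
    if pred_present and len(pred_present) != len(PRED_COLUMNS):
        raise SchemaError(
            f"{path}: predicted-count block is partial; need all of {PRED_COLUMNS} or none"
        )

    records = []
    for rownum, (_, row) in enumerate(df.iterrows(), start=2):  # 1-based incl. header
        try:
            manual = _parse_counts(row, MANUAL_COLUMNS, rownum)
            predicted = _parse_counts(row, PRED_COLUMNS, rownum) if pred_present else None
            rec = SpecimenRecord(
                id=str(row["id"]), year=int(row["year"]), doy=int(row["doy"]),
                latitude=float(row["latitude"]), longitude=float(row["longitude"]),
                elevation=float(row["elevation"]), spring_tmax=float(row["spring_tmax"]),
                winter_ppt=float(row["winter_ppt"]),
                manual_counts=manual, predicted_counts=predicted,
            )
        except (ValueError, TypeError) as exc:
            raise SchemaError(f"{path}: row {rownum}: {exc}") from exc
        records.append(rec)
    logger.info("read %d specimen(s) from %s", len(records), path)
    return records


def write_specimens(records: Sequence[SpecimenRecord], path: str | Path,
                    header_comment: str | None = None) -> None:
    """Write records as a canonical CSV (pred_* block included when present)."""
    rows = []
    any_pred = any(r.predicted_counts is not None for r in records)
    some_pred = any_pred and not all(r.predicted_counts is not None for r in records)
    if some_pred:
        raise ValueError("cannot write a table where only some records have predicted counts")
    for r in records:
        row = dict(id=r.id, year=r.year, doy=r.doy, latitude=r.latitude,
                   longitude=r.longitude, elevation=r.elevation,
                   spring_tmax=r.spring_tmax, winter_ppt=r.winter_ppt)
        row.update(zip(MANUAL_COLUMNS, r.manual_counts.as_tuple()))
        if any_pred:
            row.update(zip(PRED_COLUMNS, r.predicted_counts.as_tuple()))  # type: ignore[union-attr]
        rows.append(row)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        # %.17g keeps coordinates and climate values bit-exact on re-read
        pd.DataFrame(rows).to_csv(fh, index=False, float_format="%.17g")
    logger.info("wrote %d specimen(s) to %s", len(records), path)


def counts_from_coco(
    json_path: str | Path,
    category_map: Mapping[str, str],
    strict: bool = True,
) -> pd.DataFrame:
    """Reduce COCO-style instance annotations to per-image organ counts.

    ``category_map`` maps the annotation set's category names to canonical
    organ classes (``{"flower bud": "buds", ...}``).  With ``strict`` an
    unmapped category raises; otherwise it is counted into an
    ``unmapped`` column and reported.  Images bearing no annotations get
    all-zero rows.

    Returns a DataFrame indexed by ``image_id`` with one column per organ
    class (plus ``unmapped`` when applicable).
    """
    with open(json_path, encoding="utf-8") as fh:
        try:
            payload = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ValueError(f"{json_path}: malformed JSON: {exc}") from exc
    for key in ("images", "annotations", "categories"):
        if key not in payload:
            raise ValueError(f"{json_path}: missing COCO section {key!r}")

    bad_targets = set(category_map.values()) - set(ORGAN_CLASSES)
    if bad_targets:
        raise ValueError(f"category map targets unknown organ classes: {sorted(bad_targets)}")
    cat_to_class = {}
    unmapped_names = []
    for cat in payload["categories"]:
        cls = category_map.get(cat["name"])
        if cls is None:
            unmapped_names.append(cat["name"])
            if strict:
                raise ValueError(f"unmapped category {cat['name']!r} (strict mode)")
        cat_to_class[cat["id"]] = cls
    if unmapped_names:
        logger.warning("unmapped categories counted as 'unmapped': %s", unmapped_names)

    cols = list(ORGAN_CLASSES) + (["unmapped"] if unmapped_names else [])
    counts = pd.DataFrame(0, index=[img["id"] for img in payload["images"]],
                          columns=cols, dtype=int)
    counts.index.name = "image_id"
    for ann in payload["annotations"]:
        cls = cat_to_class.get(ann["category_id"])
        counts.loc[ann["image_id"], cls if cls else "unmapped"] += 1
    return counts


def load_config(path: str | Path) -> dict:
    """Load a TOML run configuration."""
    with open(path, "rb") as fh:
        return tomllib.load(fh)


def _simulation_config(block: Mapping) -> SimulationConfig:
    known = SimulationConfig.__dataclass_fields__
    unknown = set(block) - set(known)
    if unknown:
        raise ValueError(f"unknown simulate option(s): {sorted(unknown)}")
    coerced = {
        k: tuple(v) if isinstance(known[k].default, tuple) else v
        for k, v in block.items()
    }
    return SimulationConfig(**coerced)


def run_pipeline(config: Mapping, outdir: str | Path) -> Path:
    """Run the full analysis chain and write an artifact directory.

    ``config`` contains either an ``input`` key (path to a specimen CSV)
    or a ``simulate`` table of :class:`SimulationConfig` fields.  Outputs:
    the (simulated) specimen table, PI tables per available count source,
    and — when predicted counts exist — the detector evaluation report and
    the four model fits with their comparisons, plus the resolved config.
    Deterministic for a fixed config.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    try:
        if "simulate" in config:
            stage = "simulate"
            sim_cfg = _simulation_config(config["simulate"])
            records = simulate_collection(sim_cfg)
            write_specimens(records, outdir / "specimens.csv",
                            header_comment=f"simulated collection; seed={sim_cfg.seed}")
            resolved = {"simulate": asdict(sim_cfg)}
        elif "input" in config:
            stage = "read"
            records = read_specimens(config["input"], rename=config.get("rename"))
            resolved = {"input": str(config["input"])}
        else:
            raise ValueError("config needs either an 'input' path or a [simulate] block")

        stage = "score"
        pi_table(records, "manual").to_csv(outdir / "pi_manual.csv", index=False)
        have_pred = all(r.predicted_counts is not None for r in records)
        if any(r.predicted_counts is not None for r in records) and not have_pred:
            raise ValueError("some but not all records carry predicted counts")
        if have_pred:
            pi_table(records, "predicted").to_csv(outdir / "pi_predicted.csv", index=False)

            stage = "evaluate"
            evaluation.evaluation_report(records).to_csv(outdir / "evaluation.csv", index=False)
            age_rows = [evaluation.age_effect(records, t)
                        for t in list(ORGAN_CLASSES) + ["pi"]]
            pd.DataFrame([vars(a) for a in age_rows]).to_csv(
                outdir / "age_effects.csv", index=False)

            stage = "model"
            fits = {}
            for source in ("manual", "predicted"):
                fits[("temporal", source)] = models.temporal_shift_model(records, source)
                fits[("climate", source)] = models.phenoclimatic_model(records, source)
            pd.concat([models.model_report(f) for f in fits.values()]).to_csv(
                outdir / "models.csv", index=False)

            stage = "report"
            _write_derived(fits, outdir / "derived_quantities.txt")
        elif config.get("evaluate") or config.get("model"):
            raise ValueError("evaluation/modelling requested but input has no pred_* block")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc

    with open(outdir / "run_config.json", "w", encoding="utf-8") as fh:
        json.dump(resolved, fh, indent=2, sort_keys=True)
    logger.info("pipeline artifacts written to %s", outdir)
    return outdir


def _write_derived(fits: Mapping, path: Path) -> None:
    lines = []
    year_cis = [fits[("temporal", s)].ci("year") for s in ("manual", "predicted")]
    lo, hi = models.shift_per_century(year_cis)
    lines.append(f"flowering-date shift over the past century: {lo:.1f} to {hi:.1f} days")
    pi_cis = [f.ci("pi") for f in fits.values()]
    derived = models.progression_days(pi_cis)
    u = derived["days_per_pi_unit"]
    c = derived["full_cycle_days"]
    lines.append(f"phenological progression: {u[0]:.1f} to {u[1]:.1f} days per PI unit")
    lines.append(f"full bud-to-ripe-fruit cycle: {c[0]:.1f} to {c[1]:.1f} days")
    for fam in ("temporal", "climate"):
        cmp_ = models.compare_models(fits[(fam, "manual")], fits[(fam, "predicted")])
        lines.append(
            f"{fam} models, manual vs predicted PI: all 95% CIs overlap = {cmp_.all_overlap}"
        )
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
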