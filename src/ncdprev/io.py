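"""Delimited-text serialisation of survey frames with a column-role
sidecar, and CSV round-trips for projections, prevalence series and
completed sets."""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
import yaml

from .synthetic import DEMOGRAPHIC_COLS, SURVEY_COLS

COLUMN_ROLES = {
    **{c: "demographic" for c in DEMOGRAPHIC_COLS},
    **{c: "survey" for c in SURVEY_COLS},
    "participation": "participation",
    "source": "wave-source",
}


def write_frame(frame: pd.DataFrame, path: str | Path) -> Path:
    """Write a survey frame as CSV (empty field = missing) with a YAML
    sidecar naming each column's role."""
    path = Path(path)
    frame.to_csv(path, index=False)
    roles = {c: COLUMN_ROLES.get(c, "other") for c in frame.columns}
    sidecar = path.with_suffix(path.suffix + ".schema.yaml")
    sidecar.write_text(yaml.safe_dump({"columns": roles}, sort_keys=False))
    return path


def read_frame(path: str | Path) -> pd.DataFrame:
    """Read a survey frame written by :func:`write_frame`; the sidecar,
    when present, fixes the column set."""
    path = Path(path)
    frame = pd.read_csv(path)
    sidecar = path.with_suffix(path.suffix + ".schema.yaml")
    if sidecar.exists():
        roles = yaml.safe_load(sidecar.read_text())["columns"]
        missing = [c for c in roles if c not in frame.columns]
        if missing:
            raise ValueError(f"frame lacks columns named in schema: {missing}")
    return frame


def write_completed_set(completed, directory: str | Path) -> Path:
    """One CSV per completed imputation plus JSON run metadata and the
    chain-mean diagnostics."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for i, f in enumerate(completed.frames):
        f.to_csv(directory / f"imputation_{i:03d}.csv", index=False)
    meta = {
        "m": completed.config.m,
        "iterations": completed.config.iterations,
        "seed": completed.config.seed,
        "specs": [
            {"target": s.target, "sampler": s.sampler,
             "predictors": list(s.predictors),
             "year_form": s.year_term.form,
             "year_knots": list(s.year_term.knots)}
            for s in completed.specs
        ],
    }
    (directory / "metadata.json").write_text(json.dumps(meta, indent=2))
    completed.chain_stats.to_csv(directory / "chain_means.csv", index=False)
    return directory


def specs_to_yaml(specs, path: str | Path) -> Path:
    """Persist chosen imputation specs for a later run."""
    path = Path(path)
    payload = [
        {"target": s.target, "sampler": s.sampler,
         "predictors": list(s.predictors),
         "year_form": s.year_term.form,
         "year_knots": list(s.year_term.knots)}
        for s in specs
    ]
    path.write_text(yaml.safe_dump(payload, sort_keys=False))
    return path


def specs_from_yaml(path: str | Path):
    from .formula import YearTerm
    from .mice import ImputationSpec

    payload = yaml.safe_load(Path(path).read_text())
    return [
        ImputationSpec(
            target=d["target"], sampler=d["sampler"],
            predictors=tuple(d["predictors"]),
            year_term=YearTerm(d["year_form"], tuple(d.get("year_knots", ()))),
        )
        for d in payload
    ]
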