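"""End-to-end orchestration of the synthetic study.

One master seed drives every stage (design -> cohort simulation ->
optional per-subject refits -> exclusion filters -> correlation
heatmap -> mediation -> serial path model); re-running with the same
config and seed reproduces every artifact byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort import CohortConfig, generate_cohort, cohort_to_frame
from .fitting import fit_map
from .mediation import simple_mediation, serial_path_model
from .stats import (block_exclusion, correlation_heatmap, plot_heatmap,
                    subject_exclusion)

MISSING_SENTINEL = ""  # empty CSV cell; missing values are never imputed

#: cohort-table schema: column -> numpy dtype kind(s)
COHORT_SCHEMA = {
    "id": "iu",
    "plasma_lactate": "f",
    "dmpfc_lactate": "f",
    "ains_lactate": "f",
    "ech_beta_dmpfc": "f",
    "ech_beta_ains": "f",
    "prop_HE": "f",
    "prop_HPE": "f",
    "prop_HME": "f",
    "kR": "f", "kP": "f", "kEp": "f", "kEm": "f",
    "kFp": "f", "kLm": "f", "kBias": "f",
}
OPTIONAL_COLUMNS = ("ains_lactate", "ech_beta_ains")

DEFAULT_HEATMAP_VARS = [
    "plasma_lactate", "dmpfc_lactate", "ains_lactate",
    "ech_beta_dmpfc", "kEp", "kEm", "prop_HE", "prop_HPE", "prop_HME",
]


class SchemaError(ValueError):
    pass


@dataclass
class RunConfig:
    cohort: CohortConfig = field(default_factory=CohortConfig)
    seed: int = 0
    out_dir: str | None = None
    fit_subjects: bool = False
    heatmap_variables: list[str] = field(
        default_factory=lambda: list(DEFAULT_HEATMAP_VARS))
    mediation_xmy: tuple[str, str, str] = (
        "dmpfc_lactate", "ech_beta_dmpfc", "prop_HPE")
    path_chain: tuple[str, str, str, str] = (
        "plasma_lactate", "dmpfc_lactate", "ech_beta_dmpfc", "prop_HPE")
    render_figures: bool = False


def _config_hash(config: RunConfig) -> str:
    def default(o):
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        return str(o)

    blob = json.dumps(dataclasses.asdict(config), sort_keys=True,
                      default=default)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_pipeline(config: RunConfig | None = None) -> dict:
    """Run every stage and return the structured report.

    Every exclusion is attributed to a named rule; artifacts are
    written under ``config.out_dir`` when set.
    """
    cfg = config or RunConfig()
    rng = np.random.default_rng(cfg.seed)
    cohort_seed = int(rng.integers(2**31 - 1))
    fit_seed = int(rng.integers(2**31 - 1))

    subjects = generate_cohort(cfg.cohort, seed=cohort_seed)
    table = cohort_to_frame(subjects)

    # behavior-based exclusions, attributed per rule
    all_choices = pd.concat(
        [s.choices.assign(subject=s.id) for s in subjects], ignore_index=True)
    excl_subjects = subject_exclusion(all_choices)
    excluded_blocks = {
        s.id: block_exclusion(s.choices) for s in subjects
        if block_exclusion(s.choices)
    }
    table = table.loc[~table["id"].isin(excl_subjects)].reset_index(drop=True)

    if cfg.fit_subjects:
        fits = {}
        for s in subjects:
            if s.id in excl_subjects:
                continue
            res = fit_map(s.choices, seed=fit_seed + s.id, n_restarts=3)
            fits[s.id] = res.estimates.to_dict()
        fitted = pd.DataFrame.from_dict(fits, orient="index")
        fitted.index.name = "id"
        for col in fitted.columns:
            table[f"fitted_{col}"] = table["id"].map(fitted[col])

    heatmap = correlation_heatmap(table, cfg.heatmap_variables)
    x, m, y = cfg.mediation_xmy
    med_tab = table[[x, m, y]].dropna()
    med = simple_mediation(med_tab[x], med_tab[m], med_tab[y])
    p1, p2, p3, p4 = cfg.path_chain
    path_tab = table[[p1, p2, p3, p4]].dropna()
    path = serial_path_model(path_tab[p1], path_tab[p2], path_tab[p3],
                             path_tab[p4], names=cfg.path_chain)

    report = {
        "provenance": {
            "package_version": __version__,
            "config_hash": _config_hash(cfg),
            "seed": cfg.seed,
        },
        "cohort": {
            "n_generated": cfg.cohort.n_subjects,
            "n_after_subject_exclusion": int(len(table)),
            "excluded_subjects_rule_he95": sorted(excl_subjects),
            "excluded_blocks_rule_94": {
                int(k): list(v) for k, v in excluded_blocks.items()},
            "complete_n": {
                v: int(table[v].notna().sum())
                for v in ("plasma_lactate", "dmpfc_lactate", "ains_lactate")
            },
        },
        "heatmap": {
            "r": heatmap["r"].round(10).to_dict(),
            "p": heatmap["p"].round(10).to_dict(),
            "n": heatmap["n"].astype(int).to_dict(),
        },
        "mediation": dataclasses.asdict(med),
        "path_model": dataclasses.asdict(path),
    }

    if cfg.out_dir is not None:
        out = Path(cfg.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        save_cohort_table(table, out / "cohort.csv")
        for key in ("r", "p", "n"):
            heatmap[key].to_csv(out / f"heatmap_{key}.csv",
                                float_format="%.10g")
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
        if cfg.render_figures:
            plot_heatmap(heatmap, out / "heatmap.png")
    return report


# -- schema-validated table I/O ----------------------------------------


def save_cohort_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False, na_rep=MISSING_SENTINEL,
                 float_format="%.12g")


def load_cohort_table(path) -> pd.DataFrame:
    """Load a cohort CSV, validating the documented schema.

    Missing optional columns come back as all-missing; type violations
    are reported with their column and first offending row.
    """
    df = pd.read_csv(path)
    errors = []
    for col, kinds in COHORT_SCHEMA.items():
        if col not in df.columns:
            if col in OPTIONAL_COLUMNS:
                df[col] = np.nan
                continue
            errors.append(f"missing required column {col!r}")
            continue
        if df[col].dtype.kind not in kinds + ("f" if "i" in kinds else ""):
            bad = df[col].apply(
                lambda v: not isinstance(v, (int, float, np.number)))
            row = int(bad.idxmax()) if bad.any() else 0
            errors.append(
                f"column {col!r}: expected numeric, got "
                f"{df[col].dtype} (see row {row})")
    if errors:
        raise SchemaError("; ".join(errors))
    return df
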