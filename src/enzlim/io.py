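"""Reading and writing the survey file formats.

All tables are plain delimited text, UTF-8, "." decimal, header row
mandatory:

* ``chemistry.csv`` — comma-separated site chemistry, columns exactly
  ``site_id,water_depth,...,sed_tp``;
* ``enzymes.csv`` — comma-separated activities, columns
  ``site_id,bg,cbh,nag,lap,ap``;
* ``bacteria.tsv`` / ``fungi.tsv`` — tab-separated counts, first column
  ``site_id``, remaining columns taxon identifiers, integer cells.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import pandas as pd

from .community import TaxonTable
from .stoichiometry import ENZYME_NAMES, EnzymeProfile, SiteChemistry, ValidationError
from .synthetic import SurveyConfig, SyntheticSurvey

__all__ = [
    "FormatError",
    "AlignmentError",
    "CHEMISTRY_COLUMNS",
    "ENZYME_COLUMNS",
    "write_survey",
    "read_chemistry",
    "read_enzymes",
    "read_taxon_table",
    "read_tables",
]

CHEMISTRY_COLUMNS = (
    "site_id", "water_depth", "secchi_depth", "water_temp", "water_salinity",
    "water_ph", "water_cond", "water_do", "water_tn", "water_tp",
    "sed_ph", "sed_cond", "sed_tc", "sed_tn", "sed_tp",
)
ENZYME_COLUMNS = ("site_id",) + ENZYME_NAMES


class FormatError(ValueError):
    """Raised when a file does not match its declared schema."""


class AlignmentError(ValueError):
    """Raised when input tables do not share the same ordered site ids."""


def _read_delimited(path: str | Path, sep: str, required: Sequence[str] | None,
                    name: str) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"{name} file not found: {path}")
    try:
        df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    except Exception as exc:  # pandas raises several parse error types
        raise FormatError(f"could not parse {name} file {path}: {exc}") from exc
    if required is not None:
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise FormatError(
                f"{name} file {path} is missing column(s): {missing}"
            )
        extra = [c for c in df.columns if c not in required]
        if extra:
            raise FormatError(f"{name} file {path} has unknown column(s): {extra}")
    if "site_id" not in df.columns or df.columns[0] != "site_id":
        raise FormatError(f"{name} file {path} must have 'site_id' as first column")
    return df


def read_chemistry(path: str | Path) -> list[SiteChemistry]:
    df = _read_delimited(path, ",", CHEMISTRY_COLUMNS, "chemistry")
    return [
        SiteChemistry(site_id=str(row["site_id"]),
                      **{c: float(row[c]) for c in CHEMISTRY_COLUMNS[1:]})
        for _, row in df.iterrows()
    ]


def read_enzymes(path: str | Path) -> list[EnzymeProfile]:
    df = _read_delimited(path, ",", ENZYME_COLUMNS, "enzymes")
    return [
        EnzymeProfile(site_id=str(row["site_id"]),
                      **{e: float(row[e]) for e in ENZYME_NAMES})
        for _, row in df.iterrows()
    ]


def read_taxon_table(path: str | Path, name: str = "taxon table") -> TaxonTable:
    df = _read_delimited(path, "\t", None, name)
    df = df.set_index("site_id")
    df.index = df.index.astype(str)
    try:
        return TaxonTable(df)
    except ValidationError as exc:
        raise FormatError(f"{name} file {path}: {exc}") from exc


def _check_alignment(site_lists: dict[str, list[str]]) -> list[str]:
    items = list(site_lists.items())
    ref_name, ref = items[0]
    for name, ids in items[1:]:
        if ids != ref:
            missing = sorted(set(ref) - set(ids))
            surplus = sorted(set(ids) - set(ref))
            detail = []
            if missing:
                detail.append(f"absent from {name}: {missing}")
            if surplus:
                detail.append(f"absent from {ref_name}: {surplus}")
            if not detail:
                detail.append("site order differs")
            raise AlignmentError(
                f"site ids in {name} do not match {ref_name} ({'; '.join(detail)})"
            )
    return ref


def read_tables(
    chemistry_path: str | Path,
    enzymes_path: str | Path,
    bacteria_path: str | Path | None = None,
    fungi_path: str | Path | None = None,
):
    """Read and align all survey inputs.

    Returns ``(chemistry, enzymes, bacteria, fungi)``; the taxon tables are
    ``None`` when their paths are.  Raises :class:`AlignmentError` listing
    the offending sites when the tables do not share the same ordered ids.
    """
    chemistry = read_chemistry(chemistry_path)
    enzymes = read_enzymes(enzymes_path)
    bacteria = read_taxon_table(bacteria_path, "bacteria") if bacteria_path else None
    fungi = read_taxon_table(fungi_path, "fungi") if fungi_path else None
    site_lists = {
        "chemistry": [c.site_id for c in chemistry],
        "enzymes": [e.site_id for e in enzymes],
    }
    if bacteria is not None:
        site_lists["bacteria"] = bacteria.site_ids
    if fungi is not None:
        site_lists["fungi"] = fungi.site_ids
    _check_alignment(site_lists)
    return chemistry, enzymes, bacteria, fungi


def write_survey(survey: SyntheticSurvey, out_dir: str | Path) -> dict[str, Path]:
    """Write a survey as chemistry.csv, enzymes.csv, bacteria.tsv, fungi.tsv
    and truth.json (the generating parameters); returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "chemistry": out / "chemistry.csv",
        "enzymes": out / "enzymes.csv",
        "bacteria": out / "bacteria.tsv",
        "fungi": out / "fungi.tsv",
        "truth": out / "truth.json",
    }
    # %.17g round-trips IEEE doubles exactly
    chem = pd.DataFrame([dataclasses.asdict(c) for c in survey.chemistry])
    chem[list(CHEMISTRY_COLUMNS)].to_csv(
        paths["chemistry"], index=False, float_format="%.17g"
    )
    enz = pd.DataFrame([dataclasses.asdict(e) for e in survey.enzymes])
    enz[list(ENZYME_COLUMNS)].to_csv(
        paths["enzymes"], index=False, float_format="%.17g"
    )
    for key, table in (("bacteria", survey.bacteria), ("fungi", survey.fungi)):
        table.counts.rename_axis("site_id").to_csv(paths[key], sep="\t")
    truth = dataclasses.asdict(survey.truth)
    truth["log_mean_activity"] = dict(survey.truth.log_mean_activity)
    paths["truth"].write_text(json.dumps(truth, indent=2, sort_keys=True) + "\n")
    return paths


def read_truth(path: str | Path) -> SurveyConfig:
    """Round-trip a truth.json back into a SurveyConfig."""
    raw = json.loads(Path(path).read_text())
    raw["salinity_range"] = tuple(raw["salinity_range"])
    raw["ph_range"] = tuple(raw["ph_range"])
    raw["tn_water_lognormal"] = tuple(raw["tn_water_lognormal"])
    raw["tp_sed_lognormal"] = tuple(raw["tp_sed_lognormal"])
    raw["log_mean_activity"] = tuple(sorted(raw["log_mean_activity"].items()))
    return SurveyConfig(**raw)
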