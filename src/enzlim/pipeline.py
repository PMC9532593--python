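"""End-to-end survey analysis: limitation indices → community linkage → stats.

:func:`run_analyze` mirrors the standard workflow of a sediment
enzyme-stoichiometry survey:

1. acquisition sums and the vector analysis per site;
2. water-column Redfield classification;
3. richness and Bray–Curtis dissimilarity per microbial group;
4. element-cycle distance and scalar difference matrices, Mantel tests
   linking community turnover to enzyme-allocation turnover;
5. Pearson / OLS / quadratic screens of every limitation index, enzyme and
   acquisition sum against every chemistry covariate;
6. stepwise predictor screening for the C- and N-limitation indices.

Every output is a plain-text table; given identical inputs, config and seed
the outputs are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .community import MantelResult, TaxonTable, bray_curtis, mantel, richness
from .io import read_tables
from .stats import QuadShape, ols, pearson, quadratic_fit, stepwise
from .stoichiometry import (
    ENZYME_NAMES,
    EnzymeProfile,
    SiteChemistry,
    ValidationError,
    VectorLimitation,
    acquisition_sums,
    element_cycle_distance,
    scalar_difference_matrix,
    vector_limitation,
    water_limitation,
)

__all__ = ["AnalysisConfig", "AnalysisReport", "run_analyze", "summarize_limitation"]

CHEMISTRY_COVARIATES = (
    "water_depth", "secchi_depth", "water_temp", "water_salinity", "water_ph",
    "water_cond", "water_do", "water_tn", "water_tp",
    "sed_ph", "sed_cond", "sed_tc", "sed_tn", "sed_tp",
)

#: Default candidate set for the stepwise screens (all chemistry covariates).
STEPWISE_CANDIDATES = CHEMISTRY_COVARIATES


@dataclass(frozen=True)
class AnalysisConfig:
    """Inputs and knobs of one analysis run."""

    chemistry_path: str
    enzymes_path: str
    bacteria_path: str | None = None
    fungi_path: str | None = None
    out_dir: str | None = None
    standardize_element_distance: bool = True
    mantel_permutations: int = 999
    seed: int = 0
    balanced_tolerance: float = 1e-9
    bray_curtis_mode: str = "counts"
    stepwise_direction: str = "both"
    stepwise_criterion: str = "aic"
    stepwise_candidates: tuple[str, ...] = STEPWISE_CANDIDATES

    def __post_init__(self) -> None:
        if self.mantel_permutations < 99:
            raise ValidationError(
                f"mantel_permutations must be ≥ 99, got {self.mantel_permutations}"
            )
        unknown = set(self.stepwise_candidates) - set(CHEMISTRY_COVARIATES)
        if unknown:
            raise ValidationError(f"unknown stepwise candidate(s): {sorted(unknown)}")


@dataclass
class AnalysisReport:
    """All tables produced by one run, plus provenance."""

    limitation: pd.DataFrame
    water: pd.DataFrame
    richness: pd.DataFrame | None
    summary: dict
    correlations: pd.DataFrame
    regressions: pd.DataFrame
    quadratic: pd.DataFrame
    stepwise: pd.DataFrame
    mantel: pd.DataFrame | None
    provenance: dict
    log: list[str] = field(default_factory=list)


def summarize_limitation(vlims: Sequence[VectorLimitation]) -> dict:
    """Survey-level summary of the per-site vector analysis.

    Reports the means of vector length, angle and N limitation, the count of
    each limitation class, and the mean per-site fraction of total enzyme
    activity directed toward C acquisition, C/(C+N+P) — recovered from the
    proportions as 1/(1/x + 1/y − 1).
    """
    if not vlims:
        raise ValidationError("summarize_limitation needs at least one site")
    classes = {"N_LIMITED": 0, "P_LIMITED": 0, "BALANCED": 0}
    for v in vlims:
        classes[v.limitation_class.value] += 1
    c_fractions = [1.0 / (1.0 / v.x + 1.0 / v.y - 1.0) for v in vlims]
    n = len(vlims)
    return {
        "n_sites": n,
        "mean_vector_length": sum(v.vector_length for v in vlims) / n,
        "mean_vector_angle_deg": sum(v.vector_angle_deg for v in vlims) / n,
        "mean_n_limitation": sum(v.n_limitation for v in vlims) / n,
        "limitation_class_counts": classes,
        "mean_c_fraction": sum(c_fractions) / n,
    }


def _mantel_seed(base_seed: int, index: int) -> int:
    return int(np.random.SeedSequence([base_seed, index]).generate_state(1)[0] % (2**31))


def _screen_tables(limits: pd.DataFrame, chem: pd.DataFrame):
    """Pearson / linear OLS / quadratic screens of responses vs covariates."""
    responses = (
        ["vector_length", "vector_angle_deg", "n_limitation"]
        + list(ENZYME_NAMES)
        + ["c_acq", "n_acq", "p_acq"]
    )
    corr_rows, reg_rows, quad_rows = [], [], []
    # the C-vs-N limitation trade-off is part of the screen
    pairs = [(r, c) for r in responses for c in CHEMISTRY_COVARIATES]
    pairs.append(("vector_length", "n_limitation"))
    for resp, pred in pairs:
        y = limits[resp].to_numpy()
        x = (limits if pred in limits.columns else chem)[pred].to_numpy()
        cr = pearson(x, y)
        corr_rows.append(
            {"response": resp, "predictor": pred, "r": cr.r,
             "p_value": cr.p_value, "n": cr.n}
        )
        fit = ols(y, pd.DataFrame({pred: x}))
        for term in fit.params.index:
            reg_rows.append(
                {"response": resp, "terms": f"linear:{term}",
                 "coef": fit.params[term], "se": fit.bse[term],
                 "t": fit.tvalues[term], "p": fit.pvalues[term],
                 "r2": fit.r_squared, "adj_r2": fit.adj_r_squared}
            )
        qf = quadratic_fit(y, x)
        for term in qf.fit.params.index:
            reg_rows.append(
                {"response": resp, "terms": f"quadratic:{pred}:{term}",
                 "coef": qf.fit.params[term], "se": qf.fit.bse[term],
                 "t": qf.fit.tvalues[term], "p": qf.fit.pvalues[term],
                 "r2": qf.fit.r_squared, "adj_r2": qf.fit.adj_r_squared}
            )
        quad_rows.append(
            {"response": resp, "predictor": pred, "a": qf.a, "b": qf.b,
             "c": qf.c, "vertex_x": qf.vertex_x,
             "c_pvalue": float(qf.fit.pvalues["x2"]), "shape": qf.shape.value}
        )
    return pd.DataFrame(corr_rows), pd.DataFrame(reg_rows), pd.DataFrame(quad_rows)


def run_analyze(config: AnalysisConfig) -> AnalysisReport:
    """Run the full analysis described in the module docstring.

    Reads and aligns the inputs, computes every table, optionally writes them
    to ``config.out_dir`` (limitation.tsv, water.tsv, richness.tsv,
    summary.json, correlations.tsv, regressions.tsv, quadratic.tsv,
    stepwise.tsv, mantel.tsv, run.log) and returns the in-memory report.
    """
    log: list[str] = [f"enzlim {__version__} analyze"]
    chemistry, enzymes, bacteria, fungi = read_tables(
        config.chemistry_path, config.enzymes_path,
        config.bacteria_path, config.fungi_path,
    )
    site_ids = [c.site_id for c in chemistry]
    log.append(f"read {len(site_ids)} aligned sites")

    # 1. vector analysis per site
    sums = [acquisition_sums(e) for e in enzymes]
    vlims = [vector_limitation(s, config.balanced_tolerance) for s in sums]
    limitation = pd.DataFrame(
        {
            "site_id": site_ids,
            "c_acq": [s.c_acq for s in sums],
            "n_acq": [s.n_acq for s in sums],
            "p_acq": [s.p_acq for s in sums],
            "x": [v.x for v in vlims],
            "y": [v.y for v in vlims],
            "vector_length": [v.vector_length for v in vlims],
            "vector_angle_deg": [v.vector_angle_deg for v in vlims],
            "n_limitation": [v.n_limitation for v in vlims],
            "limitation_class": [v.limitation_class.value for v in vlims],
        }
    )
    for e, prof in zip(ENZYME_NAMES, zip(*[p.as_array() for p in enzymes])):
        limitation[e] = prof  # enzyme columns kept in memory for the screens

    # 2. water Redfield classification
    water_rows = []
    for c in chemistry:
        w = water_limitation(c.water_tn, c.water_tp)
        water_rows.append(
            {"site_id": c.site_id, "water_tn": w.tn, "water_tp": w.tp,
             "np_molar_ratio": w.np_molar_ratio,
             "water_limitation": w.water_limitation.value}
        )
    water = pd.DataFrame(water_rows)

    summary = summarize_limitation(vlims)
    summary["water_limitation_counts"] = (
        water["water_limitation"].value_counts().to_dict()
    )

    # 3–4. community metrics and Mantel linkage
    rich_df = None
    mantel_df = None
    groups = [(g, t) for g, t in (("bacteria", bacteria), ("fungi", fungi))
              if t is not None]
    if groups:
        rich_df = pd.DataFrame({"site_id": site_ids})
        for gname, table in groups:
            rich_df[gname] = richness(table).to_numpy()
        element_d = element_cycle_distance(
            enzymes, standardize=config.standardize_element_distance
        )
        scalar_targets = {
            "element_cycle": element_d,
            "c_acq": scalar_difference_matrix(limitation["c_acq"], site_ids),
            "n_acq": scalar_difference_matrix(limitation["n_acq"], site_ids),
            "p_acq": scalar_difference_matrix(limitation["p_acq"], site_ids),
            "vector_length": scalar_difference_matrix(
                limitation["vector_length"], site_ids),
            "n_limitation": scalar_difference_matrix(
                limitation["n_limitation"], site_ids),
        }
        rows = []
        idx = 0
        for gname, table in groups:
            bc = bray_curtis(table, mode=config.bray_curtis_mode)
            for tname, dmat in scalar_targets.items():
                seed_i = _mantel_seed(config.seed, idx)
                idx += 1
                res = mantel(
                    bc, dmat, n_perm=config.mantel_permutations, seed=seed_i
                )
                rows.append(
                    {"pair": f"{gname}_vs_{tname}",
                     "matrix_a": f"{gname}_bray_curtis", "matrix_b": tname,
                     "r": res.r, "p_value": res.p_value,
                     "n_perm": res.n_perm, "seed": seed_i}
                )
        mantel_df = pd.DataFrame(rows)
        log.append(f"ran {len(rows)} Mantel tests "
                   f"({config.mantel_permutations} permutations)")

    # 5. univariate screens
    chem_df = pd.DataFrame([dataclasses.asdict(c) for c in chemistry])
    correlations, regressions, quadratic = _screen_tables(limitation, chem_df)
    log.append(f"screened {len(correlations)} response–predictor pairs")

    # 6. stepwise screens for the two limitation indices
    cand = chem_df[list(config.stepwise_candidates)]
    step_rows = []
    for resp in ("vector_length", "n_limitation"):
        res = stepwise(
            limitation[resp].to_numpy(), cand,
            direction=config.stepwise_direction,
            criterion=config.stepwise_criterion,
        )
        step_rows.append(
            {"response": resp, "selected": "+".join(res.selected) or "(none)",
             "criterion": res.fit.aic, "final_r2": res.fit.r_squared}
        )
    stepwise_df = pd.DataFrame(step_rows)

    provenance = {
        "version": __version__,
        "seed": config.seed,
        "config": {k: v for k, v in dataclasses.asdict(config).items()
                   if k != "out_dir"},
        "input_sha256": {
            name: hashlib.sha256(Path(p).read_bytes()).hexdigest()
            for name, p in (
                ("chemistry", config.chemistry_path),
                ("enzymes", config.enzymes_path),
                ("bacteria", config.bacteria_path),
                ("fungi", config.fungi_path),
            ) if p
        },
    }
    provenance["config_sha256"] = hashlib.sha256(
        json.dumps(provenance["config"], sort_keys=True).encode()
    ).hexdigest()
    summary["provenance"] = provenance

    report = AnalysisReport(
        limitation=limitation, water=water, richness=rich_df, summary=summary,
        correlations=correlations, regressions=regressions, quadratic=quadratic,
        stepwise=stepwise_df, mantel=mantel_df, provenance=provenance, log=log,
    )
    if config.out_dir is not None:
        _write_report(report, Path(config.out_dir))
    return report


_LIMITATION_COLUMNS = [
    "site_id", "c_acq", "n_acq", "p_acq", "x", "y",
    "vector_length", "vector_angle_deg", "n_limitation", "limitation_class",
]


def _write_report(report: AnalysisReport, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)

    def tsv(df: pd.DataFrame, name: str) -> None:
        df.to_csv(out / name, sep="\t", index=False, float_format="%.10g")

    tsv(report.limitation[_LIMITATION_COLUMNS], "limitation.tsv")
    tsv(report.water, "water.tsv")
    if report.richness is not None:
        tsv(report.richness, "richness.tsv")
    tsv(report.correlations, "correlations.tsv")
    tsv(report.regressions, "regressions.tsv")
    tsv(report.quadratic, "quadratic.tsv")
    tsv(report.stepwise, "stepwise.tsv")
    if report.mantel is not None:
        tsv(report.mantel, "mantel.tsv")
    (out / "summary.json").write_text(
        json.dumps(report.summary, indent=2, sort_keys=True) + "\n"
    )
    (out / "run.log").write_text("\n".join(report.log) + "\n")
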