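"""End-to-end analysis: cohort → forces → driving-force comparison → report.

``run_pipeline`` generates (or accepts) a cohort of area curves, computes
diastolic hydraulic force curves, summarizes the paired area differences at
the three canonical timepoints, compares the diastasis hydraulic forces with
the peak-driving-force bracket, and writes curves.csv, forces.csv and a
versioned report.json.  Everything is deterministic given the seed.

Report rounding mirrors clinical reporting conventions: forces to one
decimal newton, areas to one decimal cm², fractions to whole percent; the
unrounded values are always retained alongside.
"""

from __future__ import annotations

import json
import logging
import math
from pathlib import Path

from . import __version__
from .cohort_stats import mean_sem, three_timepoint_table
from .config import RunConfig
from .driving_force import hydraulic_fraction
from .errors import DomainError
from .geometry_synth import generate_cohort, population_mean_subject
from .hydraulics import force_curve, fraction_diastole_positive, net_hydraulic_force
from .io import write_curves_csv, write_forces_csv

__all__ = ["run_pipeline", "REPORT_SCHEMA_VERSION"]

log = logging.getLogger(__name__)

REPORT_SCHEMA_VERSION = 1


def _clean(obj, ndigits: int):
    """Round floats for a stable report and map non-finite values to None."""
    if isinstance(obj, dict):
        return {k: _clean(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_clean(v, ndigits) for v in obj]
    if isinstance(obj, float):
        if not math.isfinite(obj):
            return None
        return round(obj, ndigits)
    return obj


def run_pipeline(config: RunConfig | None = None, out_dir=None) -> dict:
    """Run the full analysis and write curves, forces and the JSON report.

    Returns the report as a dict (identical to the written JSON).
    """
    config = config or RunConfig()
    out = Path(out_dir if out_dir is not None else config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    params = config.cohort.to_params()
    pressures = config.pressures.to_model()
    log.info("seed=%d config_sha256=%s", params.seed, config.sha256())

    cohort = generate_cohort(params)
    write_curves_csv(cohort, out / "curves.csv")
    fcs = [force_curve(s, pressures) for s in cohort]
    write_forces_csv(cohort, fcs, out / "forces.csv")

    summary = three_timepoint_table(cohort)

    # per-subject hydraulic force at mid diastasis, both VSA definitions
    t_dd = params.phases.t_dd
    forces_dd = {}
    for name, chamber in (("endo", "vsa_endo"), ("epi", "vsa_epi")):
        vals = [
            net_hydraulic_force(s.curve(chamber).area_at(t_dd), s.asa.area_at(t_dd),
                                pressures.p_lv, pressures.p_la)
            for s in cohort
        ]
        if len(vals) >= 2:
            mean, sem = mean_sem(vals)
        else:
            mean, sem = float(vals[0]), float("nan")
        forces_dd[name] = {"mean_N": mean, "sem_N": sem, "n": len(vals)}

    # positive-force fraction of diastole on the population-mean curves
    fc_mean = force_curve(population_mean_subject(params), pressures)
    frac = {w: fraction_diastole_positive(fc_mean, w) for w in ("endo", "epi")}

    dfe = config.driving_force.to_estimate()
    frac_unrounded = hydraulic_fraction(
        forces_dd["endo"]["mean_N"], forces_dd["epi"]["mean_N"],
        dfe.force_min, dfe.force_max,
    )
    # headline ratio: whole-newton hydraulic forces against the 5-10 N bracket
    fh_lo, fh_hi = round(forces_dd["endo"]["mean_N"]), round(forces_dd["epi"]["mean_N"])
    try:
        frac_rounded = hydraulic_fraction(fh_lo, fh_hi, dfe.force_min, dfe.force_max)
    except DomainError:
        frac_rounded = (None, None)

    nd = config.report_precision
    report = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "provenance": {
            "package": "avhyd",
            "version": __version__,
            "seed": params.seed,
            "config_sha256": config.sha256(),
        },
        "cohort": {
            "n_subjects": params.n_subjects,
            "n_frames": params.n_frames,
            "statistics": _clean(summary.to_records(), nd),
        },
        "area_differences_diastasis_cm2": _clean(
            {
                name: {
                    "mean": summary.row("mid_diastasis", f"delta_{name}")["mean"],
                    "sem": summary.row("mid_diastasis", f"delta_{name}")["sem"],
                    "mean_rounded": round(summary.row("mid_diastasis", f"delta_{name}")["mean"], 1),
                }
                for name in ("endo", "epi")
            },
            nd,
        ),
        "hydraulic_force_diastasis_N": _clean(
            {
                name: {**forces_dd[name], "mean_rounded_N": round(forces_dd[name]["mean_N"], 1)}
                for name in ("endo", "epi")
            },
            nd,
        ),
        "fraction_diastole_positive": _clean(
            {
                "endo": frac["endo"],
                "epi": frac["epi"],
                "endo_pct_rounded": round(100 * frac["endo"]),
                "epi_pct_rounded": round(100 * frac["epi"]),
            },
            nd,
        ),
        "driving_force": _clean(
            {
                "f_per_mass_mN_g": dfe.f_per_mass,
                "lv_mass_g": dfe.lv_mass,
                "load_range_g": [dfe.load_min, dfe.load_max],
                "force_range_N": [dfe.force_min, dfe.force_max],
            },
            nd,
        ),
        "hydraulic_fraction": _clean(
            {
                "rounded": list(frac_rounded),
                "rounded_pct": [
                    None if f is None else round(100 * f) for f in frac_rounded
                ],
                "unrounded": list(frac_unrounded),
            },
            nd,
        ),
    }
    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    return report
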