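"""Pipeline drivers and cohort-level aggregation reports.

Provides the full record -> spectrum -> fits pipeline, heart-rate-group
summary tables of the goodness-of-fit metrics (mean +/- SD per model),
and the dynamic-compliance comparison: fractional pseudo-capacitance
evaluated at the heart pulsation w_h = 2*pi/T against the classical
compliance estimates, with ordinary least-squares regressions per
pairing.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .waveform import HemodynamicRecord
from .harmonics import decompose, impedance_spectrum, ImpedanceSpectrum
from .calibration import FitConfig, FitResult, fit_model
from .models import MODEL_TAGS, foc_compliance, voigt_compliance
from .cohort import CohortSpec, VirtualSubject, generate_cohort

__all__ = [
    "spectrum_from_record",
    "fit_record",
    "GroupSummary",
    "cohort_benchmark",
    "group_summary_table",
    "ComplianceComparison",
    "compliance_comparison",
    "compliance_entries",
    "compliance_from_entries",
]

log = logging.getLogger("fracwk")

METRIC_NAMES = ("nrmse", "re_moduli_pct", "re_phase_pct", "deviation_pct")


def spectrum_from_record(
    record: HemodynamicRecord, N: int = 20
) -> ImpedanceSpectrum:
    """Empirical impedance spectrum of one record (decompose P and Q, ratio)."""
    Ps = decompose(record.pressure, N)
    Qs = decompose(record.flow, N)
    return impedance_spectrum(Ps, Qs)


def fit_record(
    record: HemodynamicRecord,
    models=MODEL_TAGS,
    cfg: FitConfig | None = None,
) -> dict[str, FitResult]:
    """Fit the requested models to one record's impedance spectrum."""
    cfg = cfg or FitConfig()
    Z = spectrum_from_record(record, cfg.N)
    log.info(
        "record %s: N=%d harmonics, G=%.4g mmHg*s/ml",
        record.subject_id,
        cfg.N,
        float(Z.Z[0].real),
    )
    out = {}
    for tag in models:
        res = fit_model(Z, tag, cfg)
        log.info(
            "record %s: %s NRMSE=%.3e converged=%s",
            record.subject_id,
            tag,
            res.metrics.nrmse,
            res.converged,
        )
        out[tag] = res
    return out


@dataclass(frozen=True)
class GroupSummary:
    """Mean +/- SD of each metric for one heart-rate group and model."""

    hr: float
    model: str
    n: int
    means: dict
    sds: dict


def cohort_benchmark(
    spec: CohortSpec,
    models=MODEL_TAGS,
    cfg: FitConfig | None = None,
):
    """Generate a cohort, fit every model to every subject, aggregate.

    Returns ``(subjects, fits, summaries)`` where ``fits`` maps
    subject_id -> {model: FitResult} and ``summaries`` is a list of
    GroupSummary.  Subjects whose fits all fail are excluded with a
    logged count.
    """
    cfg = cfg or FitConfig()
    subjects = generate_cohort(spec)
    fits: dict[str, dict[str, FitResult]] = {}
    n_failed = 0
    for s in subjects:
        try:
            fits[s.record.subject_id] = fit_record(s.record, models, cfg)
        except Exception as e:  # total failure for this subject
            n_failed += 1
            log.warning("subject %s excluded: %s", s.record.subject_id, e)
    if n_failed:
        log.warning("%d subject(s) excluded from aggregation", n_failed)
    summaries = []
    for hr in spec.hr_set:
        ids = [
            s.record.subject_id
            for s in subjects
            if s.HR == hr and s.record.subject_id in fits
        ]
        for tag in models:
            vals = {m: [] for m in METRIC_NAMES}
            for sid in ids:
                r = fits[sid][tag].metrics
                for m in METRIC_NAMES:
                    vals[m].append(getattr(r, m))
            means = {m: float(np.mean(v)) for m, v in vals.items()}
            sds = {m: float(np.std(v, ddof=0)) for m, v in vals.items()}
            summaries.append(
                GroupSummary(hr=hr, model=tag, n=len(ids), means=means, sds=sds)
            )
    return subjects, fits, summaries


def group_summary_table(summaries) -> pd.DataFrame:
    """Heart-rate-group table: {model} x {metric} x {mean, sd} columns."""
    rows = {}
    for g in summaries:
        row = rows.setdefault(g.hr, {"hr": g.hr, "n": g.n})
        for m in METRIC_NAMES:
            row[f"{g.model}_{m}_mean"] = g.means[m]
            row[f"{g.model}_{m}_sd"] = g.sds[m]
    return pd.DataFrame(sorted(rows.values(), key=lambda r: r["hr"]))


@dataclass(frozen=True)
class ComplianceComparison:
    """Per-subject compliance estimates and pairwise OLS regressions.

    ``table`` has one row per subject with the fractional dynamic
    compliance at the heart pulsation (modulus, real, imaginary), the
    classical compliances C_W2, C_W3, C_VW, and the Voigt dynamic
    compliance at the heart pulsation.  ``regressions`` maps pairing
    names to (slope, intercept, r_squared).
    """

    table: pd.DataFrame
    regressions: dict


_PAIRINGS = (
    ("CF_mod", "C_W2"),
    ("CF_mod", "C_W3"),
    ("CF_mod", "C_VW"),
    ("CF_re", "Cc_re"),
    ("CF_im", "Cc_im"),
    ("CF_mod", "Cc_mod"),
)


def compliance_entries(
    subjects_T: dict[str, float],
    fits: dict[str, dict[str, FitResult]],
) -> list[dict]:
    """Flatten fitted physical parameters into compliance-report entries."""
    entries = []
    for sid, T in subjects_T.items():
        f = fits[sid]
        missing = [m for m in MODEL_TAGS if m not in f]
        if missing:
            raise ValueError(f"subject {sid} lacks fits for {missing}")
        if any(f[m].params is None for m in MODEL_TAGS):
            log.warning("subject %s has a non-physical extraction; skipped", sid)
            continue
        pf, pv = f["fwk2"].params, f["vwk"].params
        entries.append(
            {
                "subject_id": sid,
                "T": T,
                "C_alpha": pf.C_alpha,
                "alpha": pf.alpha,
                "C_W2": f["wk2"].params.C,
                "C_W3": f["wk3"].params.C,
                "C_VW": pv.C_vw,
                "Rd": pv.Rd,
            }
        )
    return entries


def compliance_comparison(
    subjects_T: dict[str, float],
    fits: dict[str, dict[str, FitResult]],
) -> ComplianceComparison:
    """Compare compliance estimates across models at each subject's w_h.

    Parameters
    ----------
    subjects_T : mapping subject_id -> heart period T (s).
    fits : mapping subject_id -> {model: FitResult}, all four models.
    """
    return compliance_from_entries(compliance_entries(subjects_T, fits))


def compliance_from_entries(entries: list[dict]) -> ComplianceComparison:
    """Compliance report from flat per-subject parameter entries.

    Each entry needs subject_id, T, C_alpha, alpha, C_W2, C_W3, C_VW, Rd.
    """
    rows = []
    for e in entries:
        wh = 2.0 * np.pi / e["T"]
        CF = foc_compliance(e["C_alpha"], e["alpha"], wh)
        Cc = voigt_compliance(e["C_VW"], e["Rd"], wh)
        rows.append(
            {
                "subject_id": e["subject_id"],
                "omega_h": wh,
                "CF_mod": abs(CF),
                "CF_re": CF.real,
                "CF_im": CF.imag,
                "C_W2": e["C_W2"],
                "C_W3": e["C_W3"],
                "C_VW": e["C_VW"],
                "Cc_mod": abs(Cc),
                "Cc_re": Cc.real,
                "Cc_im": Cc.imag,
            }
        )
    table = pd.DataFrame(rows)
    regressions = {}
    if len(table) < 3:
        warnings.warn(
            "fewer than 3 subjects: compliance regressions skipped", stacklevel=2
        )
    else:
        for ykey, xkey in _PAIRINGS:
            x = table[xkey].to_numpy()
            y = table[ykey].to_numpy()
            if np.ptp(x) == 0:
                continue
            lr = stats.linregress(x, y)
            regressions[f"{ykey}~{xkey}"] = (
                float(lr.slope),
                float(lr.intercept),
                float(lr.rvalue**2),
            )
    return ComplianceComparison(table=table, regressions=regressions)
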