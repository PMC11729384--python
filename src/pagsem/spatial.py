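"""Department-level aggregation for prevalence/adherence mapping.

Produces join-ready attribute tables (one row per department code):
expansion-factor-weighted obesity prevalence with quartile bins, unweighted
median adherence scores per latent with quartile bins, and an
above-national-average flag. Choropleth rendering is left to external GIS
tools; an optional helper injects the attributes into a GeoJSON template by
feature code.
"""

from __future__ import annotations

import json
import warnings

import numpy as np
import pandas as pd

from .descriptives import weighted_prevalence
from .errors import DomainError
from .scores import LatentScores

__all__ = ["quartile_bins", "department_summary", "inject_geojson_attributes"]


def quartile_bins(values, tie_break=None) -> np.ndarray:
    """Quartile bins 1-4 by rank, deterministic tie-break by input order
    (or by the ``tie_break`` key), group sizes differing by at most one.

    An all-constant input is degenerate: every value lands in bin 1 with a
    warning.
    """
    values = np.asarray(values, dtype=float)
    n = values.size
    if n < 4:
        raise DomainError("quartile binning needs at least 4 values")
    if np.all(values == values[0]):
        warnings.warn("degenerate value distribution; all quartile bins set to 1",
                      RuntimeWarning, stacklevel=2)
        return np.ones(n, dtype=int)
    if tie_break is None:
        order = np.argsort(values, kind="stable")
    else:
        order = np.lexsort((np.asarray(tie_break), values))
    ranks = np.empty(n, dtype=int)
    ranks[order] = np.arange(n)
    return (4 * ranks) // n + 1


def department_summary(
    records: pd.DataFrame,
    scores: LatentScores | None = None,
    weight_col: str = "expansion_factor",
    department_col: str = "department",
    outcome_col: str = "obesity",
    expected_departments=None,
) -> pd.DataFrame:
    """Per-department weighted obesity prevalence (%) and median adherence.

    Rows are sorted by department code; the national weighted prevalence is
    appended as a constant column with a per-department above/below flag.
    Departments listed in ``expected_departments`` but absent from the data
    are omitted with a warning.
    """
    if department_col not in records:
        raise DomainError(f"records are missing the {department_col!r} column")
    df = records.reset_index(drop=True)
    w = (
        df[weight_col].to_numpy(dtype=float)
        if weight_col in df
        else np.ones(len(df))
    )
    y = df[outcome_col].to_numpy(dtype=float)
    national = weighted_prevalence(y, w)
    codes = df[department_col].astype(str).to_numpy()
    if expected_departments is not None:
        missing = sorted(set(map(str, expected_departments)) - set(codes))
        if missing:
            warnings.warn(
                f"departments with zero records omitted: {', '.join(missing)}",
                RuntimeWarning, stacklevel=2,
            )
    rows = []
    for code in sorted(set(codes)):
        mask = codes == code
        est = weighted_prevalence(y[mask], w[mask])
        row = {
            "department": code,
            "n": int(mask.sum()),
            "n_effective": est.n_effective,
            "prevalence_pct": 100.0 * est.estimate,
            "prevalence_ci_low_pct": 100.0 * est.ci_low,
            "prevalence_ci_high_pct": 100.0 * est.ci_high,
        }
        if scores is not None:
            for latent in scores.latents:
                row[f"median_score_{latent}"] = float(
                    np.median(scores.means(latent)[mask])
                )
        rows.append(row)
    out = pd.DataFrame(rows)
    # quartile bins need at least four departments; few-department tables
    # (common in tests and subgroup analyses) carry no bin
    def _bins(values):
        if len(out) < 4:
            return np.full(len(out), np.nan)
        return quartile_bins(values, tie_break=out["department"].to_numpy())

    out["prevalence_quartile"] = _bins(out["prevalence_pct"].to_numpy())
    if scores is not None:
        for latent in scores.latents:
            out[f"adherence_quartile_{latent}"] = _bins(
                out[f"median_score_{latent}"].to_numpy()
            )
    out["national_prevalence_pct"] = 100.0 * national.estimate
    out["above_national"] = out["prevalence_pct"] > out["national_prevalence_pct"]
    return out


def inject_geojson_attributes(
    summary: pd.DataFrame, template_path, out_path, code_property: str = "code"
) -> int:
    """Copy per-department attributes into matching GeoJSON features.

    Features are matched on ``properties[code_property]`` against the
    summary's department codes; returns the number of features updated.
    """
    with open(template_path) as fh:
        gj = json.load(fh)
    by_code = {str(r["department"]): r for r in summary.to_dict("records")}
    updated = 0
    for feature in gj.get("features", []):
        code = str(feature.get("properties", {}).get(code_property, ""))
        if code in by_code:
            attrs = {k: v for k, v in by_code[code].items() if k != "department"}
            feature.setdefault("properties", {}).update(attrs)
            updated += 1
    with open(out_path, "w") as fh:
        json.dump(gj, fh)
    return updated
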