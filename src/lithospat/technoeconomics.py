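"""Assemblage accounting: inventory tables and the flake-deficit ratios.

The ratio system quantifies on-site vs off-site artifact flow:

* **FRR** (flake recovery rate): observed flakes as a percentage of the
  negative scars counted on cores -- a flake deficit (FRR < 100) suggests
  products were carried off-site, a surplus (FRR > 100) that flakes were
  brought in or cores removed;
* **flake-to-core ratio**: flakes (plain, fragmented and retouched)
  divided by handheld cores;
* **retouch-to-flake ratio**: retouched flakes divided by plain whole
  flakes.

Percentages are reported to two decimals with round-half-up; printed
sources sometimes truncate instead, so comparisons against published
tables should allow ±0.01.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import SchemaError
from .reference import CATEGORIES, MATERIALS

CONDITIONS = ("R0", "R1", "R2")

REQUIRED_COLUMNS = ("id", "x", "y", "category", "raw_material")
OPTIONAL_COLUMNS = ("subtype", "mass", "condition", "z", "scars", "reduction_model")


def round2(x):
    """Round half *up* to 2 decimals (0.005 -> 0.01), elementwise."""
    return np.floor(np.asarray(x, float) * 100.0 + 0.5) / 100.0


class ArtifactCatalog:
    """Validated tabular lithic inventory.

    Thin wrapper over a DataFrame enforcing the documented schema: required
    columns (id, x, y, category, raw_material), closed category and
    raw-material vocabularies, and non-negative masses where present.
    """

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"catalog is missing required column(s): {missing}")
        bad_cat = sorted(set(df["category"].dropna()) - set(CATEGORIES))
        if bad_cat:
            raise SchemaError(f"unknown lithic categor(ies): {bad_cat}")
        bad_mat = sorted(set(df["raw_material"].dropna()) - set(MATERIALS))
        if bad_mat:
            raise SchemaError(f"unknown raw material(s): {bad_mat}")
        if "mass" in df.columns:
            m = pd.to_numeric(df["mass"], errors="coerce")
            if (m.dropna() < 0).any():
                raise SchemaError("negative mass values present")
        if "condition" in df.columns:
            bad_cond = sorted(
                set(df["condition"].dropna()) - set(CONDITIONS)
            )
            if bad_cond:
                raise SchemaError(f"unknown condition code(s): {bad_cond}")
        self.df = df.reset_index(drop=True)

    def __len__(self):
        return len(self.df)

    def counts(self, by) -> pd.Series:
        return self.df.groupby(list(by)).size()


def assemblage_table(catalog: ArtifactCatalog | pd.DataFrame) -> pd.DataFrame:
    """Category × raw-material cross-tabulation with totals and percentages.

    Rows are the lithic categories, columns the raw materials plus
    ``total_n`` and ``total_pct`` (percent of the grand total, two decimals
    round-half-up); a ``total`` row closes the table.  Row order follows the
    canonical category vocabulary, so the table is invariant to catalog row
    order.
    """
    df = catalog.df if isinstance(catalog, ArtifactCatalog) else ArtifactCatalog(catalog).df
    if len(df) == 0:
        raise ValueError("empty catalog")
    ct = pd.crosstab(df["category"], df["raw_material"])
    ct = ct.reindex(index=list(CATEGORIES), columns=list(MATERIALS), fill_value=0)
    grand = ct.to_numpy().sum()
    out = ct.copy()
    out["total_n"] = ct.sum(axis=1)
    out["total_pct"] = round2(100.0 * out["total_n"] / grand)
    total_row = out.sum(axis=0)
    total_row.name = "total"
    out = pd.concat([out, total_row.to_frame().T])
    out.loc["total", "total_pct"] = 100.0
    mat_pct = round2(100.0 * ct.sum(axis=0).to_numpy() / grand)
    out.loc["total_pct_materials"] = [*mat_pct, grand, np.nan]
    return out


@dataclass(frozen=True)
class RatioReport:
    """Per-material and total flake ratios.

    ``table`` has one row per raw material plus ``total``; columns:
    expected, observed, frr, flake_to_core, retouch_to_flake.  Undefined
    ratios (zero denominators) are NaN with the reason recorded in
    ``notes``.
    """

    table: pd.DataFrame
    notes: tuple = ()

    def value(self, row: str, col: str) -> float:
        return float(self.table.loc[row, col])


def flake_ratios(
    expected: dict,
    observed: dict,
    cores: dict,
    retouched: dict,
    plain_whole: dict,
    expected_total: float | None = None,
) -> RatioReport:
    """Assemble the flake-ratio report from per-material counts.

    ``expected`` are negative-scar counts on cores, ``observed`` the flakes
    recovered (plain + fragmented + retouched), ``cores`` the handheld core
    counts, ``retouched``/``plain_whole`` the retouch-ratio inputs.  Totals
    default to the per-material sums; ``expected_total`` may override the
    expected-flake total when the source total is carried separately from
    its per-material breakdown.
    """
    mats = list(expected.keys())
    notes = []
    rows = {}
    for m in mats:
        rows[m] = _ratio_row(
            expected.get(m, 0), observed.get(m, 0), cores.get(m, 0),
            retouched.get(m, 0), plain_whole.get(m, 0), m, notes,
        )
    e_tot = sum(expected.values()) if expected_total is None else expected_total
    if expected_total is not None and expected_total != sum(expected.values()):
        notes.append(
            f"expected total {expected_total} carried from source; per-material "
            f"breakdown sums to {sum(expected.values())}"
        )
    rows["total"] = _ratio_row(
        e_tot, sum(observed.values()), sum(cores.values()),
        sum(retouched.values()), sum(plain_whole.values()), "total", notes,
    )
    table = pd.DataFrame(rows).T
    return RatioReport(table, tuple(notes))


def _ratio_row(exp, obs, cor, ret, plain, name, notes):
    row = {"expected": exp, "observed": obs}
    if exp > 0:
        row["frr"] = round2(100.0 * obs / exp)
    else:
        row["frr"] = np.nan
        notes.append(f"{name}: FRR undefined (no expected flakes)")
    if cor > 0:
        row["flake_to_core"] = round2(obs / cor)
    else:
        row["flake_to_core"] = np.nan
        notes.append(f"{name}: flake-to-core undefined (no cores)")
    if plain > 0:
        row["retouch_to_flake"] = round2(ret / plain)
    else:
        row["retouch_to_flake"] = np.nan
        notes.append(f"{name}: retouch-to-flake undefined (no plain whole flakes)")
    return row


def core_productivity(core_records: pd.DataFrame, by=("raw_material",)) -> pd.DataFrame:
    """Mean negative-scar count per core within each grouping.

    ``core_records`` needs a ``scars`` column plus the grouping columns
    (e.g. raw material and/or reduction model).  Returns group, sample size
    and the mean; empty groups are simply absent.
    """
    df = core_records.dropna(subset=["scars"])
    if df.empty:
        raise ValueError("no cores with scar counts")
    g = df.groupby(list(by))["scars"]
    out = pd.DataFrame({"n_cores": g.size(), "mean_scars": g.mean(), "total_scars": g.sum()})
    return out.reset_index()


def missing_flake_fraction(expected_total: float, observed_total: float):
    """Percentage of theoretically expected flakes missing from the site.

    Returns ``(headline, exact, surplus_flag)``: the headline value is
    rounded to the nearest integer, the exact value keeps full precision.
    A negative value (surplus of flakes over scars) is allowed and flagged.
    """
    if expected_total <= 0:
        raise ValueError("expected_total must be positive")
    exact = 100.0 * (1.0 - observed_total / expected_total)
    surplus = observed_total > expected_total
    headline = int(np.floor(exact + 0.5)) if exact >= 0 else -int(np.floor(-exact + 0.5))
    return headline, exact, surplus


def reference_ratio_report() -> RatioReport:
    """Flake-ratio report recomputed from the published DS inputs."""
    from . import reference as ref

    return flake_ratios(
        ref.SCAR_TOTALS,
        ref.OBSERVED_FLAKES,
        {m: ref.HANDHELD_CORES[m] for m in ("basalt", "phonolite", "quartzite")},
        ref.RETOUCHED,
        ref.PLAIN_WHOLE,
        expected_total=ref.EXPECTED_TOTAL,
    )
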