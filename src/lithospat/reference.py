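"""Published inventory counts of the DS Level 22B lithic assemblage.

These integer counts are the printed inputs of the techno-economic ratio
system: the category × raw-material inventory, the handheld/bipolar core
breakdown by reduction model, the negative-scar totals counted on cores,
and the observed flake counts.  The synthetic fixture reproduces them
exactly by construction, and the ratio reports recompute every derived
percentage and ratio from them at run time.

Two printed quirks are preserved deliberately (they matter for reproducing
the published ratios):

* the *handheld* phonolite core count is 20 in the core-study breakdown but
  21 in the inventory table; the flake-to-core ratios are computed on the
  core-study subtotals (108/20/34), which reproduce the published values;
* the printed total of expected flakes (negative scars) is 771 although the
  per-material scar counts sum to 726; the headline missing-flake figure
  uses the printed total, so it is carried as an explicit total here.
"""

from __future__ import annotations

import pandas as pd

MATERIALS = ("basalt", "phonolite", "quartzite", "other")
CATEGORIES = (
    "unmodified",
    "percussion",
    "core",
    "detached",
    "retouched",
    "chopper",
    "waste",
)

#: (category, subtype, per-material counts) of the full inventory; counts in
#: the order basalt, phonolite, quartzite, other.  Cells sum to 1,229.
_CELLS = (
    ("unmodified", "cobble", (111, 3, 4, 1)),
    ("unmodified", "broken_cobble", (7, 0, 2, 0)),
    ("unmodified", "cobble_fragment", (5, 0, 0, 0)),
    ("percussion", "hammerstone", (26, 6, 1, 0)),
    ("percussion", "broken_hammerstone", (1, 0, 0, 0)),
    ("percussion", "percussion_flake", (4, 4, 4, 0)),
    ("percussion", "anvil", (2, 0, 0, 0)),
    ("percussion", "mbb", (0, 0, 6, 0)),
    ("core", "handheld", (108, 21, 33, 1)),
    ("core", "bipolar", (0, 0, 14, 0)),
    ("detached", "handheld_flake", (42, 11, 171, 3)),
    ("detached", "broken_flake", (13, 3, 97, 1)),
    ("detached", "bipolar_flake", (0, 0, 12, 0)),
    ("retouched", "retouched_flake", (6, 4, 30, 0)),
    ("chopper", "chopper", (2, 1, 1, 0)),
    ("waste", "core_flake", (1, 2, 5, 0)),
    ("waste", "flake_fragment", (2, 3, 104, 2)),
    ("waste", "shatter", (5, 0, 96, 0)),
    ("waste", "debris", (4, 1, 172, 1)),
    ("waste", "fragment", (17, 5, 45, 3)),
)


def catalog_cells():
    """Flat list of (category, subtype, material, count) with count > 0."""
    out = []
    for cat, sub, counts in _CELLS:
        for mat, c in zip(MATERIALS, counts):
            if c > 0:
                out.append((cat, sub, mat, c))
    return out


def table_counts() -> pd.DataFrame:
    """Category × raw-material counts (rows: categories, cols: materials)."""
    df = pd.DataFrame(0, index=list(CATEGORIES), columns=list(MATERIALS))
    for cat, _sub, counts in _CELLS:
        df.loc[cat] += list(counts)
    return df


TOTAL_N = 1229

#: Surface-condition counts: fresh (R0), moderately abraded (R1), rounded
#: (R2); the published condition study covers 1,197 of the 1,229 items, the
#: remainder carries no condition reading.
CONDITION_COUNTS = {"R0": 1129, "R1": 64, "R2": 4, None: 32}

#: Handheld-core counts from the core study (used for flake-to-core ratios).
HANDHELD_CORES = {"basalt": 108, "phonolite": 20, "quartzite": 34, "gneiss": 1}
BIPOLAR_CORES = 14

#: Handheld reduction-model counts per material (core-study breakdown).
#: Models: T test, UL/UO unifacial, BL/BA/BO/BC bifacial, MM multifacial,
#: E exhausted.
REDUCTION_MODELS = {
    "T": (48, 2, 5, 0),
    "UL": (22, 1, 2, 1),
    "UO": (2, 0, 2, 0),
    "BL": (18, 5, 1, 0),
    "BA": (1, 4, 0, 0),
    "BO": (5, 3, 7, 0),
    "BC": (1, 0, 1, 0),
    "MM": (9, 5, 7, 0),
    "E": (2, 0, 9, 0),
}
_MODEL_MATERIALS = ("basalt", "phonolite", "quartzite", "gneiss")

#: Negative-scar totals counted on handheld cores, per raw material.
SCAR_TOTALS = {"basalt": 433, "phonolite": 152, "quartzite": 141}

#: Printed total of expected flakes; kept distinct from sum(SCAR_TOTALS).
EXPECTED_TOTAL = 771

#: Observed flakes (plain + broken + retouched) per raw material.
OBSERVED_FLAKES = {"basalt": 61, "phonolite": 18, "quartzite": 298}
OBSERVED_TOTAL = 377

#: Retouched flakes and plain whole flakes (retouch-to-flake ratio inputs).
RETOUCHED = {"basalt": 6, "phonolite": 4, "quartzite": 30}
RETOUCHED_TOTAL = 40
PLAIN_WHOLE = {"basalt": 42, "phonolite": 11, "quartzite": 171}
PLAIN_WHOLE_TOTAL = 227


def reduction_model_shares(material: str) -> dict:
    """Reduction-model count distribution for one material's handheld cores."""
    i = _MODEL_MATERIALS.index(material)
    return {m: c[i] for m, c in REDUCTION_MODELS.items() if c[i] > 0}
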