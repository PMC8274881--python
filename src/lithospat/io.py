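"""Readers, writers, configuration and the staged analysis pipeline.

File formats: artifact catalogs as CSV (documented schema), windows as WKT
POLYGON text, rasters as ESRI ASCII grids (GIS-interoperable), summary
curves as tidy CSV, test results and the pipeline manifest as JSON,
configuration as TOML.
"""

from __future__ import annotations

import json
import logging
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import csr as csr_mod
from . import marked, summaries, synthetic, technoeconomics, uniformity
from .geometry import PointPattern, SchemaError, Window, build_pattern
from .intensity import IntensityMap, bw_likelihood_cv, kernel_intensity
from .technoeconomics import ArtifactCatalog

logger = logging.getLogger(__name__)

NODATA = -9999.0


# ---------------------------------------------------------------------------
# rasters
# ---------------------------------------------------------------------------

def write_esri_ascii(imap: IntensityMap, path) -> None:
    """ESRI ASCII grid (ncols/nrows/xllcorner/yllcorner/cellsize/NODATA)."""
    ny, nx = imap.values.shape
    vals = np.where(imap.mask & np.isfinite(imap.values), imap.values, NODATA)
    with open(path, "w") as f:
        f.write(f"ncols {nx}\nnrows {ny}\n")
        f.write(f"xllcorner {imap.xmin:.17g}\nyllcorner {imap.ymin:.17g}\n")
        f.write(f"cellsize {imap.pixel:.17g}\nNODATA_value {NODATA:.17g}\n")
        # ESRI rasters run north to south: top row first
        for r in range(ny - 1, -1, -1):
            f.write(" ".join(f"{v:.17g}" for v in vals[r]) + "\n")


def read_esri_ascii(path) -> IntensityMap:
    with open(path) as f:
        header = {}
        for _ in range(6):
            key, val = f.readline().split()
            header[key.lower()] = float(val)
        rows = [np.fromstring(line, sep=" ") for line in f if line.strip()]
    vals = np.vstack(rows)[::-1]  # back to south-first row order
    nodata = header["nodata_value"]
    mask = vals != nodata
    vals = np.where(mask, vals, np.nan)
    return IntensityMap(
        header["xllcorner"], header["yllcorner"], header["cellsize"], vals, mask
    )


# ---------------------------------------------------------------------------
# catalog and window
# ---------------------------------------------------------------------------

def read_window(path) -> Window:
    """Window from a WKT POLYGON file or a two-column x,y vertex CSV."""
    text = Path(path).read_text().strip()
    if text.upper().startswith("POLYGON"):
        return Window.from_wkt(text)
    df = pd.read_csv(path)
    return Window(tuple(map(tuple, df.iloc[:, :2].to_numpy(float))))


def write_window(window: Window, path) -> None:
    Path(path).write_text(window.to_wkt() + "\n")


def read_catalog(path, window: Window):
    """Catalog CSV -> (ArtifactCatalog, PointPattern) with row-level errors.

    Required columns: id, x, y, category, raw_material; optional: subtype,
    mass, condition, z, scars, reduction_model.  Non-numeric coordinates
    are reported with their line numbers.
    """
    df = pd.read_csv(path)
    missing = [c for c in technoeconomics.REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"catalog {path} is missing column(s): {missing}")
    for col in ("x", "y"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()]
        if len(bad):
            lines = [int(i) + 2 for i in bad[:10]]  # +2: header + 1-basing
            raise SchemaError(f"non-numeric {col!r} at file line(s) {lines}")
        df[col] = coerced
    catalog = ArtifactCatalog(df)
    mark_cols = [c for c in df.columns if c not in ("id", "x", "y")]
    pattern = build_pattern(df[["x", "y"]].to_numpy(float), window, df[mark_cols])
    return catalog, pattern


def write_catalog(catalog, path) -> None:
    df = catalog.df if isinstance(catalog, ArtifactCatalog) else catalog
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class AnalysisConfig:
    """Pipeline configuration with the conventional Monte-Carlo defaults.

    19 simulations for relabelling tests and tolerance contours, 39 for
    simulation envelopes, 199 for CSR resimulation; significance level
    0.05.
    """

    catalog_path: str | None = None
    window_path: str | None = None
    output_dir: str = "lithospat_out"
    pixel: float | None = None
    bandwidth: float | str = "cv"
    n_sim_relabel: int = 19
    n_sim_envelope: int = 39
    n_sim_csr: int = 199
    alpha: float = 0.05
    seed: int = 0
    scan_radii: tuple = (1.0, 2.0, 5.0)
    n_tiles: int = 5
    knn_k: int = 3
    n_areas: int = 3

    def __post_init__(self):
        if min(self.n_sim_relabel, self.n_sim_envelope, self.n_sim_csr) < 1:
            raise ValueError("n_sim values must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")

    @classmethod
    def from_toml(cls, path) -> "AnalysisConfig":
        with open(path, "rb") as f:
            raw = tomllib.load(f)
        cfg = cls(**raw)
        for p in (cfg.catalog_path, cfg.window_path):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(p)
        return cfg


#: Declarative mapping from comparison class to (category, subtype)
#: selectors; a ``None`` subtype selects the whole category.  The bipolar
#: class includes shatter except in the bipolar-vs-freehand comparison,
#: where shatter (ambiguous between techniques) is dropped.
ANALYSIS_CLASSES = {
    "unmodified": (("unmodified", None),),
    "modified": (
        ("percussion", None), ("core", None), ("detached", None),
        ("retouched", None), ("chopper", None), ("waste", None),
    ),
    "percussion": (("percussion", None),),
    "handheld_knapping": (
        ("core", "handheld"), ("detached", "handheld_flake"),
        ("detached", "broken_flake"), ("retouched", None),
    ),
    "bipolar": (("core", "bipolar"), ("detached", "bipolar_flake"), ("waste", "shatter")),
    "bipolar_no_shatter": (("core", "bipolar"), ("detached", "bipolar_flake")),
    "freehand": (("core", "handheld"), ("detached", "handheld_flake")),
    "waste": (("waste", None),),
    "freehand_cores": (("core", "handheld"),),
}

#: Mass split (grams) between the light and heavy artifact fractions.
HEAVY_MASS_THRESHOLD = 400.0


def class_indicator(df: pd.DataFrame, class_name: str) -> np.ndarray:
    """Boolean row selector for a declarative analysis class."""
    sel = np.zeros(len(df), bool)
    for cat, sub in ANALYSIS_CLASSES[class_name]:
        m = df["category"].to_numpy() == cat
        if sub is not None:
            m &= df["subtype"].to_numpy() == sub
        sel |= m
    return sel


def two_class_pattern(pp: PointPattern, df: pd.DataFrame, a: str, b: str):
    """Sub-pattern of the rows in class a or b, marked 'class' = a/b."""
    ia, ib = class_indicator(df, a), class_indicator(df, b)
    keep = ia | ib
    labels = np.where(ia[keep], a, b)
    return pp.subset(np.flatnonzero(keep)).with_marks({"class": labels})


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

def _save_json(obj, path):
    with open(path, "w") as f:
        json.dump(obj, f, indent=1, default=_jsonable)
    return str(path)


def _jsonable(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serialisable: {type(o)}")


def run_pipeline(
    config: AnalysisConfig,
    catalog: ArtifactCatalog | None = None,
    pattern: PointPattern | None = None,
) -> dict:
    """Execute the staged intra-site analysis and write a JSON manifest.

    Stage order: CSR tests; per-material density maps and scan tests;
    heavy/light and modified/unmodified relative risk + segregation;
    percussion-vs-knapping, bipolar-vs-percussion, bipolar-vs-freehand and
    waste-vs-cores comparisons; the inhomogeneous G-function with
    envelopes; KNN partition + uniformity regressions; techno-economic
    tables.  A stage failure is recorded in the manifest and independent
    later stages still run.  Every randomized stage derives its seed
    deterministically from ``config.seed``.
    """
    if catalog is None or pattern is None:
        if config.catalog_path is None or config.window_path is None:
            raise ValueError("need catalog/pattern objects or paths in the config")
        window = read_window(config.window_path)
        catalog, pattern = read_catalog(config.catalog_path, window)
    df = catalog.df
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"outputs": {}, "errors": {}, "seed": config.seed, "stages": []}
    root_rng = np.random.default_rng(config.seed)
    stage_seeds = {
        name: int(root_rng.integers(2**31))
        for name in (
            "csr", "scan", "mass_risk", "modified", "percussion", "bipolar",
            "waste", "ginhom", "partition",
        )
    }

    def stage(name, fn):
        manifest["stages"].append(name)
        try:
            fn()
        except Exception as exc:  # keep independent stages running
            logger.exception("stage %s failed", name)
            manifest["errors"][name] = f"{type(exc).__name__}: {exc}"

    materials = [m for m, c in df["raw_material"].value_counts().items() if c >= 10]
    multitype = df["raw_material"].nunique() > 1

    def _bw(pp_):
        if config.bandwidth == "cv":
            return bw_likelihood_cv(pp_).selected
        return float(config.bandwidth)

    # ---- CSR tests -------------------------------------------------------
    def s_csr():
        q = csr_mod.quadrat_test(pattern, config.n_tiles)
        hs = csr_mod.hopkins_skellam(
            pattern, seed=stage_seeds["csr"], n_sim=config.n_sim_csr
        )
        manifest["outputs"]["csr_tests"] = _save_json(
            {"quadrat": q.to_dict(), "hopkins_skellam": hs.to_dict()},
            out / "csr_tests.json",
        )

    stage("csr", s_csr)

    # ---- densities and scan tests per material ---------------------------
    def s_density():
        report = {}
        for mat in materials:
            sub = pattern.subset(np.flatnonzero(df["raw_material"].to_numpy() == mat))
            h = _bw(sub)
            imap = kernel_intensity(sub, h, pixel=config.pixel)
            p = out / f"density_{mat}.asc"
            write_esri_ascii(imap, p)
            manifest["outputs"][f"density_{mat}"] = str(p)
            report[mat] = {"bandwidth": h, "n": sub.n}
        manifest["outputs"]["density_report"] = _save_json(report, out / "density_report.json")

    stage("density", s_density)

    def s_scan():
        rng = np.random.default_rng(stage_seeds["scan"])
        report = {}
        for mat in materials[:2]:
            sub = pattern.subset(np.flatnonzero(df["raw_material"].to_numpy() == mat))
            sig, results = csr_mod.significant_cluster_radii(
                sub, config.scan_radii, n_sim=config.n_sim_relabel, seed=rng,
                alpha=config.alpha,
            )
            report[mat] = {
                "significant_radii": sig,
                "tests": [r.to_dict() for r in results],
            }
        manifest["outputs"]["scan_tests"] = _save_json(report, out / "scan_tests.json")

    stage("scan", s_scan)

    # ---- two-class comparisons ------------------------------------------
    def two_class_stage(name, class_a, class_b, seed, nn_orders=8):
        def run():
            cmp_pp = two_class_pattern(pattern, df, class_a, class_b)
            if np.unique(cmp_pp.mark("class")).size < 2:
                manifest["errors"][name] = "fewer than two classes present; skipped"
                return
            rng = np.random.default_rng(seed)
            h = _bw(cmp_pp)
            field = marked.tolerance_contours(
                cmp_pp, "class", h, n_sim=config.n_sim_relabel,
                alpha=config.alpha, seed=rng, pixel=config.pixel,
            )
            seg = marked.segregation_test(
                cmp_pp, "class", h, n_sim=config.n_sim_relabel, seed=rng
            )
            nne = marked.nn_equality(
                cmp_pp, "class", class_a, class_b,
                k_max=min(nn_orders, cmp_pp.n - 1), cumulative=True,
                n_sim=config.n_sim_relabel, seed=rng,
            )
            base = out / name
            for lvl in field.levels:
                rp = f"{base}_risk_{lvl}.asc"
                write_esri_ascii(
                    IntensityMap(field.xmin, field.ymin, field.pixel,
                                 np.where(field.mask, field.prob(lvl), np.nan),
                                 field.mask),
                    rp,
                )
                manifest["outputs"][f"{name}_risk_{lvl}"] = rp
                mp = f"{base}_sigmask_{lvl}.asc"
                write_esri_ascii(
                    IntensityMap(field.xmin, field.ymin, field.pixel,
                                 field.sig_mask(lvl).astype(float), field.mask),
                    mp,
                )
                manifest["outputs"][f"{name}_sigmask_{lvl}"] = mp
            nne.to_frame().to_csv(f"{base}_nnequality.csv", index=False)
            manifest["outputs"][f"{name}_nnequality"] = f"{base}_nnequality.csv"
            manifest["outputs"][f"{name}_tests"] = _save_json(
                {
                    "segregation": seg.to_dict(),
                    "nn_equality_p": nne.p_value,
                    "bandwidth": h,
                },
                f"{base}_tests.json",
            )

        stage(name, run)

    if multitype:
        # heavy vs light fraction
        def s_mass():
            mass = pd.to_numeric(df.get("mass"), errors="coerce")
            ok = mass.notna().to_numpy()
            lab = np.where(mass.to_numpy() > HEAVY_MASS_THRESHOLD, "heavy", "light")
            sub = pattern.subset(np.flatnonzero(ok)).with_marks({"class": lab[ok]})
            if np.unique(sub.mark("class")).size < 2:
                manifest["errors"]["mass_risk"] = "single mass class; skipped"
                return
            h = _bw(sub)
            seg = marked.segregation_test(
                sub, "class", h, n_sim=config.n_sim_relabel, seed=stage_seeds["mass_risk"]
            )
            manifest["outputs"]["mass_segregation"] = _save_json(
                {"segregation": seg.to_dict(), "threshold_g": HEAVY_MASS_THRESHOLD},
                out / "mass_segregation.json",
            )

        stage("mass_risk", s_mass)
        two_class_stage("modified_vs_unmodified", "modified", "unmodified", stage_seeds["modified"])
        two_class_stage("knapping_vs_percussion", "handheld_knapping", "percussion", stage_seeds["percussion"])
        two_class_stage("bipolar_vs_percussion", "bipolar", "percussion", stage_seeds["bipolar"])
        two_class_stage("bipolar_vs_freehand", "bipolar_no_shatter", "freehand", stage_seeds["bipolar"] + 1)
        two_class_stage("waste_vs_cores", "waste", "freehand_cores", stage_seeds["waste"])
    else:
        manifest["errors"]["multitype"] = "single raw material; multitype stages skipped"

    # ---- inhomogeneous G with envelopes ----------------------------------
    def s_ginhom():
        rng = np.random.default_rng(stage_seeds["ginhom"])
        report = {}
        for mat in materials[:2]:
            sub = pattern.subset(np.flatnonzero(df["raw_material"].to_numpy() == mat))
            h = _bw(sub)
            imap = kernel_intensity(sub, h, pixel=config.pixel)
            sim = synthetic.intensity_map_simulator(imap, sub.window)
            r_grid = summaries.default_r_grid(sub)

            def stat(pp_, _imap=imap, _r=r_grid):
                return summaries.g_inhom(pp_, _imap, _r)

            curve = summaries.envelope(sub, stat, sim, n_sim=config.n_sim_envelope, seed=rng)
            p = out / f"ginhom_{mat}.csv"
            curve.to_frame().to_csv(p, index=False)
            manifest["outputs"][f"ginhom_{mat}"] = str(p)
            report[mat] = {"global_p": curve.p_value, "bandwidth": h}
        manifest["outputs"]["ginhom_report"] = _save_json(report, out / "ginhom_report.json")

    stage("ginhom", s_ginhom)

    # ---- partition + uniformity -----------------------------------------
    def s_partition():
        part = uniformity.knn_partition(pattern, k=config.knn_k, n_areas=config.n_areas)
        dfo = df.copy()
        dfo["area"] = part.labels
        p_csv = out / "catalog_with_areas.csv"
        dfo.to_csv(p_csv, index=False)
        manifest["outputs"]["catalog_with_areas"] = str(p_csv)
        sets = _default_predictor_sets(pattern, df)
        if sets:
            rep = uniformity.uniformity_report(
                _with_uniformity_marks(pattern, df), part, sets, alpha=config.alpha
            )
            manifest["outputs"]["uniformity"] = _save_json(
                rep.to_dict(), out / "uniformity.json"
            )
        else:
            manifest["errors"]["uniformity"] = "no usable categorical predictors"

    stage("partition", s_partition)

    # ---- techno-economic tables -----------------------------------------
    def s_tables():
        table = technoeconomics.assemblage_table(catalog)
        p_tab = out / "assemblage_table.csv"
        table.to_csv(p_tab)
        manifest["outputs"]["assemblage_table"] = str(p_tab)
        ratios = _catalog_ratio_report(df)
        p_rat = out / "flake_ratios.csv"
        ratios.table.to_csv(p_rat)
        manifest["outputs"]["flake_ratios"] = str(p_rat)
        if df.get("scars") is not None and df["scars"].notna().any():
            prod = technoeconomics.core_productivity(
                df[df["category"] == "core"], by=("raw_material",)
            )
            p_prod = out / "core_productivity.csv"
            prod.to_csv(p_prod, index=False)
            manifest["outputs"]["core_productivity"] = str(p_prod)

    stage("tables", s_tables)

    manifest_path = out / "manifest.json"
    _save_json(manifest, manifest_path)
    manifest["manifest_path"] = str(manifest_path)
    return manifest


def _with_uniformity_marks(pattern: PointPattern, df: pd.DataFrame) -> PointPattern:
    """Derived binary technological attributes used as regression predictors."""
    mass = pd.to_numeric(df.get("mass"), errors="coerce").to_numpy()
    marks = {
        "material_class": np.where(
            df["raw_material"].isin(["basalt", "phonolite"]), "volcanic", "quartzite_other"
        ),
        "weight_class": np.where(np.nan_to_num(mass) > 50.0, "gt50g", "le50g"),
        "knap_vs_percussion": np.where(
            class_indicator(df, "percussion"), "percussion", "knapping"
        ),
        "modified_class": np.where(
            df["category"] == "unmodified", "unmodified", "modified"
        ),
        "detached_vs_nodular": np.where(
            df["category"].isin(["detached", "retouched", "waste"]), "detached", "nodular"
        ),
        "bipolar_class": np.where(class_indicator(df, "bipolar"), "bipolar", "other"),
    }
    return pattern.with_marks(marks)


def _default_predictor_sets(pattern, df):
    if not {"category", "raw_material"}.issubset(df.columns):
        return []
    return [
        ("material_class", "weight_class", "knap_vs_percussion"),
        ("modified_class", "detached_vs_nodular", "bipolar_class"),
    ]


def _catalog_ratio_report(df: pd.DataFrame):
    """Flake-ratio report recomputed from a catalog's own rows."""
    mats = [m for m in df["raw_material"].unique() if m is not None]
    core_h = df[(df["category"] == "core") & (df.get("subtype") == "handheld")]
    expected = {
        m: float(pd.to_numeric(core_h[core_h["raw_material"] == m]["scars"], errors="coerce").sum())
        for m in mats
    }
    flakes = df[
        (df["category"].isin(["detached", "retouched"]))
        & (df.get("subtype") != "bipolar_flake")
    ]
    observed = {m: int((flakes["raw_material"] == m).sum()) for m in mats}
    cores = {m: int((core_h["raw_material"] == m).sum()) for m in mats}
    retouched = {m: int(((df["category"] == "retouched") & (df["raw_material"] == m)).sum()) for m in mats}
    plain = df[(df["category"] == "detached") & (df.get("subtype") == "handheld_flake")]
    plain_whole = {m: int((plain["raw_material"] == m).sum()) for m in mats}
    mats_pos = [m for m in mats if expected.get(m, 0) > 0 or observed.get(m, 0) > 0]
    return technoeconomics.flake_ratios(
        {m: expected[m] for m in mats_pos},
        {m: observed[m] for m in mats_pos},
        {m: cores[m] for m in mats_pos},
        {m: retouched[m] for m in mats_pos},
        {m: plain_whole[m] for m in mats_pos},
    )
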