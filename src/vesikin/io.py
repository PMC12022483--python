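"""CSV readers/writers, the bundled dataset, configuration, and the pipeline.

File conventions: comma-separated, '.' decimal, UTF-8, '#' comment lines;
column headers carry unit suffixes (``…_uM``, ``…_s1``) so units cannot
drift silently.  JSON reports keep a fixed key order for diffability and
record the seed, so every number in a report is reproducible from the
config alone.
"""

from __future__ import annotations

import importlib.resources
import json
import logging
from dataclasses import asdict, dataclass
from datetime import datetime, timezone
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import DataError, FitError
from .fitting import (
    FitConvention,
    KineticFitResult,
    fit_kobs_vs_lipid,
    stoichiometry_report,
    sweep_conventions,
)
from .geometry import (
    VesicleSpec,
    lipids_per_vesicle,
    protein_footprint,
    proteins_per_vesicle,
    surface_fraction_occupied,
    vesicle_concentration,
)
from .kinetics import BindingConditions, KineticParams
from .synthetic import (
    DEFAULT_LIPID_TOTALS,
    DEFAULT_PROTEIN_CONC,
    NoiseSpec,
    generate_kobs_dataset,
    generate_replicates,
)
from .traces import FluorescenceTrace, KobsPoint, extract_kobs_table

__all__ = [
    "TRACE_COLUMNS",
    "read_trace_csv",
    "write_trace_csv",
    "read_kobs_csv",
    "write_kobs_csv",
    "load_atdgd2_kobs",
    "AnalysisConfig",
    "run_pipeline",
    "write_report",
]

logger = logging.getLogger("vesikin")

TRACE_COLUMNS = ["time_s", "signal", "lipid_total_uM", "replicate_id"]


def _read_csv(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise DataError(f"no such file: {path}")
    try:
        return pd.read_csv(path, comment="#")
    except Exception as exc:  # noqa: BLE001
        raise DataError(f"could not parse {path}: {exc}") from exc


def _require_columns(df: pd.DataFrame, cols: Iterable[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise DataError(f"{path}: missing required columns {missing}")


def _numeric(df: pd.DataFrame, col: str, path) -> np.ndarray:
    vals = pd.to_numeric(df[col], errors="coerce")
    bad = vals.index[vals.isna() & df[col].notna()].tolist()
    if bad or vals.isna().any():
        rows = bad or vals.index[vals.isna()].tolist()
        raise DataError(f"{path}: non-numeric or missing values in '{col}' at data rows {rows[:5]}")
    return vals.to_numpy(dtype=float)


def read_trace_csv(path) -> list[FluorescenceTrace]:
    """Read fluorescence traces from CSV (time_s, signal, lipid_total_uM, replicate_id)."""
    df = _read_csv(path)
    _require_columns(df, TRACE_COLUMNS, path)
    time = _numeric(df, "time_s", path)
    signal = _numeric(df, "signal", path)
    lipid = _numeric(df, "lipid_total_uM", path)
    rep = df["replicate_id"].astype(str).to_numpy()

    traces = []
    # groups appear in file order; row order within a trace is preserved
    keys = list(dict.fromkeys(zip(lipid, rep)))
    for lt, r in keys:
        m = (lipid == lt) & (rep == r)
        rows = np.flatnonzero(m)
        try:
            traces.append(
                FluorescenceTrace(
                    time=time[m], signal=signal[m], lipid_total=lt, replicate_id=r
                )
            )
        except DataError as exc:
            raise DataError(
                f"{path}: invalid trace (lipid_total={lt}, replicate={r}, "
                f"data rows {rows[0]}..{rows[-1]}): {exc}"
            ) from exc
    return traces


def write_trace_csv(traces: Sequence[FluorescenceTrace], path) -> None:
    frames = [
        pd.DataFrame(
            {
                "time_s": tr.time,
                "signal": tr.signal,
                "lipid_total_uM": tr.lipid_total,
                "replicate_id": tr.replicate_id,
            }
        )
        for tr in traces
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_kobs_csv(path, leaflet_factor: float = 0.5) -> list[KobsPoint]:
    """Read a k_obs table from CSV.

    Accepts either a ``lipid_accessible_uM`` column, or ``lipid_total_uM``
    which is converted with ``leaflet_factor``.  ``se_s1`` is optional.
    """
    df = _read_csv(path)
    _require_columns(df, ["kobs_s1"], path)
    if "lipid_accessible_uM" in df.columns:
        acc = _numeric(df, "lipid_accessible_uM", path)
    elif "lipid_total_uM" in df.columns:
        acc = _numeric(df, "lipid_total_uM", path) * leaflet_factor
    else:
        raise DataError(f"{path}: need lipid_accessible_uM or lipid_total_uM column")
    kobs = _numeric(df, "kobs_s1", path)
    if "se_s1" in df.columns:
        # standard errors are optional per row; blank cells mean "not given"
        se = pd.to_numeric(df["se_s1"], errors="coerce").to_numpy(dtype=float)
    else:
        se = [None] * len(df)
    try:
        return [
            KobsPoint(
                lipid_accessible=a,
                k_obs=k,
                se=None if s is None or np.isnan(s) else float(s),
            )
            for a, k, s in zip(acc, kobs, se)
        ]
    except DataError as exc:
        raise DataError(f"{path}: {exc}") from exc


def write_kobs_csv(points: Sequence[KobsPoint], path) -> None:
    pd.DataFrame(
        {
            "lipid_accessible_uM": [p.lipid_accessible for p in points],
            "kobs_s1": [p.k_obs for p in points],
            "se_s1": [p.se for p in points],
        }
    ).to_csv(path, index=False)


def load_atdgd2_kobs(leaflet_factor: float = 0.5) -> list[KobsPoint]:
    """The bundled atDGD2/LUV stopped-flow k_obs dataset (six concentrations).

    Observed rates for atDGD2 binding to POPC/MGDG/POPG (70:20:10) LUVs at
    total lipid 45.5–273 μM, converted to the accessible (outer-leaflet)
    concentration with ``leaflet_factor``.
    """
    ref = importlib.resources.files("vesikin.data") / "atdgd2_kobs.csv"
    with importlib.resources.as_file(ref) as path:
        return read_kobs_csv(path, leaflet_factor=leaflet_factor)


@dataclass
class AnalysisConfig:
    """Everything a pipeline run needs; loadable from YAML.

    Exactly one data source is used, checked in this order: ``traces_csv``
    (raw traces), ``kobs_csv`` (pre-extracted table), ``simulate`` (a
    synthetic run with ``true_params``), else the bundled atDGD2 dataset.
    """

    traces_csv: str | None = None
    kobs_csv: str | None = None
    simulate: bool = False
    true_params: dict | None = None  # k_on, k_off, c1 for simulation runs
    protein_conc: float = DEFAULT_PROTEIN_CONC
    lipid_totals: tuple = DEFAULT_LIPID_TOTALS
    leaflet_factor: float = 0.5
    weighting: str = "none"
    lipid_basis: str = "accessible"
    n_starts: int = 16
    seed: int = 0
    sigma_kobs: float = 0.0
    sigma_trace: float = 0.0
    n_replicates: int = 5
    settle_decades: float | None = 3.0
    convention_sweep: bool = True
    vesicle_diameter: float = 150.0
    head_area: float = 0.6
    leaflets: int = 2
    lipids_per_vesicle_override: int | None = None

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise DataError(f"unknown config keys: {sorted(unknown)}")
        if "lipid_totals" in raw:
            raw["lipid_totals"] = tuple(raw["lipid_totals"])
        return cls(**raw)

    def vesicle_spec(self) -> VesicleSpec:
        return VesicleSpec(
            diameter=self.vesicle_diameter,
            head_area=self.head_area,
            leaflets=self.leaflets,
            lipids_per_vesicle_override=self.lipids_per_vesicle_override,
        )


def _fit_block(res: KineticFitResult) -> dict:
    return {
        "convention": {
            "protein_conc_uM": res.convention.protein_conc,
            "lipid_basis": res.convention.lipid_basis,
            "weighting": res.convention.weighting,
        },
        "k_on_uM1s1": res.params.k_on,
        "k_off_s1": res.params.k_off,
        "c1": res.params.c1,
        "kd_uM": res.kd,
        "kd_nM": res.kd * 1e3,
        "stoichiometry": stoichiometry_report(res),
        "param_se": res.param_se,
        "rss": res.rss,
        "n_points": res.n_points,
        "convergence": res.convergence,
        "seed": res.seed,
    }


def _geometry_block(config: AnalysisConfig, stoich_total: float) -> dict:
    spec = config.vesicle_spec()
    # occupancy evaluated at the highest lipid concentration of the design
    lipid_max = max(config.lipid_totals) if config.lipid_totals else 0.0
    n_lip = lipids_per_vesicle(spec)
    ves_conc = vesicle_concentration(lipid_max, spec)
    n_prot = proteins_per_vesicle(config.protein_conc, ves_conc) if ves_conc > 0 else 0.0
    footprint = protein_footprint(stoich_total, spec)
    occ = surface_fraction_occupied(n_prot, footprint, spec)
    return {
        "vesicle": asdict(spec),
        "lipids_per_vesicle": n_lip,
        "lipid_total_uM": lipid_max,
        "vesicle_conc_nM": ves_conc * 1e3,
        "proteins_per_vesicle": n_prot,
        "protein_footprint_nm2": footprint,
        "surface_fraction_occupied": occ.fraction,
        "surface_fraction_exceeds_one": occ.exceeds_surface,
    }


def _obtain_points(config: AnalysisConfig) -> tuple[list[KobsPoint], dict]:
    meta: dict = {}
    if config.traces_csv:
        logger.info("reading traces from %s", config.traces_csv)
        traces = read_trace_csv(config.traces_csv)
        cond = BindingConditions(
            protein_conc=config.protein_conc, leaflet_factor=config.leaflet_factor
        )
        extraction = extract_kobs_table(
            traces, cond, settle_decades=config.settle_decades
        )
        meta["trace_failures"] = extraction.failures
        return extraction.points, meta
    if config.kobs_csv:
        logger.info("reading k_obs table from %s", config.kobs_csv)
        return read_kobs_csv(config.kobs_csv, leaflet_factor=config.leaflet_factor), meta
    if config.simulate:
        if not config.true_params:
            raise DataError("simulate=True requires true_params {k_on, k_off, c1}")
        params = KineticParams(**config.true_params)
        logger.info("simulating k_obs dataset, sigma=%g", config.sigma_kobs)
        points = generate_kobs_dataset(
            params,
            config.protein_conc,
            config.lipid_totals,
            config.leaflet_factor,
            noise=NoiseSpec(sigma=config.sigma_kobs, seed=config.seed),
        )
        meta["true_params"] = dict(config.true_params)
        return points, meta
    logger.info("using the bundled atDGD2 stopped-flow dataset")
    meta["dataset"] = "atdgd2_kobs"
    return load_atdgd2_kobs(config.leaflet_factor), meta


def run_pipeline(config: AnalysisConfig) -> dict:
    """Chain extraction → relaxation-model fit → geometry into one report.

    The report's primary fit uses the configured convention; when
    ``convention_sweep`` is on, all combinations of protein concentration,
    lipid basis and weighting are fitted and included so the reader can
    see how the headline numbers depend on the input conventions.
    """
    points, meta = _obtain_points(config)
    if len(points) < 4:
        raise FitError(f"pipeline produced only {len(points)} usable k_obs points")

    primary_conv = FitConvention(
        config.protein_conc, config.lipid_basis, config.weighting
    )
    primary = fit_kobs_vs_lipid(
        points,
        convention=primary_conv,
        n_starts=config.n_starts,
        seed=config.seed,
        leaflet_factor=config.leaflet_factor,
    )
    logger.info(
        "primary fit: k_on=%.4g k_off=%.4g KD=%.4g nM stoich(total)=1:%d",
        primary.params.k_on,
        primary.params.k_off,
        primary.kd * 1e3,
        round(primary.stoich_total),
    )

    sweep = []
    if config.convention_sweep:
        for res in sweep_conventions(
            points,
            leaflet_factor=config.leaflet_factor,
            n_starts=config.n_starts,
            seed=config.seed,
        ):
            sweep.append(_fit_block(res))

    report = {
        "package": "vesikin",
        "version": __version__,
        "seed": config.seed,
        "input": meta,
        "kobs_table": [
            {"lipid_accessible_uM": p.lipid_accessible, "kobs_s1": p.k_obs, "se_s1": p.se}
            for p in points
        ],
        "fit": _fit_block(primary),
        "convention_sweep": sweep,
        "geometry": _geometry_block(config, primary.stoich_total),
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }
    return report


def write_report(report: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2)
        fh.write("\n")
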