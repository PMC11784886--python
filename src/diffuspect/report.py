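"""Pipeline configuration, file IO and the concentration-series report.

``build_table1_report`` regenerates the published concentration table from a
list of diffusion coefficients: Stokes-Einstein hydrodynamic radius under
the configured solvent conditions, then Perrin inversion of the (rounded)
radius at the fixed semi-major axis into a semi-minor axis, plus an
ellipsoid-volume consistency check.  Reports embed the full resolved
configuration so every number is auditable.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dosy import GAUSS_PER_CM, DecayCurve, GradientSchedule
from .hydro import (SolventConditions, ellipsoid_volume,
                    invert_perrin_semi_minor, round_half_up,
                    stokes_einstein_rh)

__all__ = ["RunConfig", "Table1Row", "build_table1_report",
           "read_decay_csv", "write_decay_csv", "write_report",
           "atomic_write_text"]


@dataclass(frozen=True)
class RunConfig:
    """Resolved parameters of a pipeline run.

    Attributes
    ----------
    temperature, viscosity : float
        Solvent conditions (K, Pa s).
    semi_major_a : float
        Fixed ellipsoid semi-major axis, nm.
    molecular_volume : float
        Reference molecular volume, nm^3.
    grid_n, grid_min, grid_max : inversion grid specification.
    regularization : float or None
        Tikhonov lambda; None selects the default (1e-3 of the kernel's
        largest singular value).
    msd_window_fraction : (float, float)
        Fit window as fractions of the largest lag.
    use_rounded_rh : bool
        Feed the 2-decimal-rounded R_h into the Perrin inversion (matches
        the published table's internal consistency); False chains at full
        precision.
    seed : int
    """

    temperature: float = 298.15
    viscosity: float = 1.00e-3
    semi_major_a: float = 2.1
    molecular_volume: float = 0.23
    grid_n: int = 256
    grid_min: float = 1e-12
    grid_max: float = 1e-8
    regularization: float | None = None
    msd_window_fraction: tuple = (0.1, 0.5)
    use_rounded_rh: bool = True
    seed: int = 0

    @property
    def conditions(self) -> SolventConditions:
        return SolventConditions(temperature=self.temperature,
                                 viscosity=self.viscosity)

    @property
    def grid(self) -> np.ndarray:
        return np.logspace(np.log10(self.grid_min), np.log10(self.grid_max),
                           self.grid_n)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["msd_window_fraction"] = list(self.msd_window_fraction)
        return d

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        """Load from JSON or YAML; unknown keys are an error."""
        text = open(path).read()
        if str(path).endswith((".yaml", ".yml")):
            import yaml
            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "msd_window_fraction" in data:
            data["msd_window_fraction"] = tuple(data["msd_window_fraction"])
        return cls(**data)


@dataclass(frozen=True)
class Table1Row:
    """One concentration of the reported series.

    ``rh`` and ``b`` carry the 2-decimal presentation values;
    ``volume_check`` is (4/3) pi a b^2 at the reported axes, rounded to two
    decimals.
    """

    concentration_mM: float
    D: float
    rh: float
    a: float
    b: float
    volume_check: float


def build_table1_report(d_values, config: RunConfig = RunConfig()
                        ) -> list[Table1Row]:
    """Concentration-series report from (concentration, D) pairs.

    Per row: R_h by Stokes-Einstein under the configured conditions; the
    semi-minor axis by Perrin inversion at the configured semi-major axis,
    taking the rounded R_h as input when ``use_rounded_rh`` is set; and the
    ellipsoid volume implied by the reported axes.
    """
    rows = []
    for conc, d in d_values:
        if not d > 0:
            raise ValueError(f"non-positive D at concentration {conc}")
        rh_full = stokes_einstein_rh(d, config.conditions)
        rh_round = round_half_up(rh_full, 2)
        rh_for_inv = rh_round if config.use_rounded_rh else rh_full
        b = invert_perrin_semi_minor(config.semi_major_a, rh_for_inv)
        b_round = round_half_up(b, 2)
        rows.append(Table1Row(
            concentration_mM=float(conc), D=float(d), rh=rh_round,
            a=config.semi_major_a, b=b_round,
            volume_check=round_half_up(
                ellipsoid_volume(config.semi_major_a, b_round), 2)))
    return rows


def read_decay_csv(path, unit: str | None = None,
                   delta: float = 2e-3, big_delta: float = 50e-3,
                   gamma: float | None = None) -> DecayCurve:
    """Read a (gradient, intensity) decay table.

    Gradient units are never guessed: the file must carry a unit-bearing
    header (``gradient_G_per_cm`` or ``gradient_T_per_m``) or the caller
    must pass ``unit`` ("G/cm" or "T/m") for a bare ``gradient`` column.
    Values are stored internally in T m^-1.  The pulse parameters complete
    the Stejskal-Tanner schedule.
    """
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    if "intensity" not in df.columns:
        raise ValueError("decay CSV must have an 'intensity' column")
    if "gradient_G_per_cm" in df.columns:
        g = df["gradient_G_per_cm"].to_numpy(dtype=float) * GAUSS_PER_CM
    elif "gradient_T_per_m" in df.columns:
        g = df["gradient_T_per_m"].to_numpy(dtype=float)
    elif "gradient" in df.columns:
        if unit in ("G/cm", "G_per_cm"):
            g = df["gradient"].to_numpy(dtype=float) * GAUSS_PER_CM
        elif unit in ("T/m", "T_per_m"):
            g = df["gradient"].to_numpy(dtype=float)
        else:
            raise ValueError(
                "gradient unit is ambiguous: use a unit-bearing column "
                "name or pass unit='G/cm' or 'T/m'")
    else:
        raise ValueError("no gradient column found")
    bad = df.index[~np.isfinite(g) | ~np.isfinite(
        df["intensity"].to_numpy(dtype=float))]
    if len(bad):
        raise ValueError(f"malformed decay row at line {bad[0] + 2}")
    kwargs = {} if gamma is None else {"gamma": gamma}
    schedule = GradientSchedule(gradients=g, delta=delta,
                                big_delta=big_delta, **kwargs)
    return DecayCurve(gradients=g,
                      intensities=df["intensity"].to_numpy(dtype=float),
                      schedule=schedule)


def write_decay_csv(decay: DecayCurve, path, unit: str = "G/cm") -> None:
    """Write a decay as CSV, in G cm^-1 (default) or T m^-1."""
    if unit in ("G/cm", "G_per_cm"):
        col, g = "gradient_G_per_cm", decay.gradients / GAUSS_PER_CM
    elif unit in ("T/m", "T_per_m"):
        col, g = "gradient_T_per_m", decay.gradients
    else:
        raise ValueError("unit must be 'G/cm' or 'T/m'")
    pd.DataFrame({col: g, "intensity": decay.intensities}).to_csv(
        path, index=False)


def atomic_write_text(text: str, path) -> None:
    """Write text to path atomically (tmp file + rename)."""
    tmp = f"{path}.tmp"
    with open(tmp, "w") as fh:
        fh.write(text)
    os.replace(tmp, path)


def write_report(rows: list[Table1Row], path, fmt: str = "csv",
                 config: RunConfig = RunConfig()) -> None:
    """Write the concentration report as CSV or JSON.

    Both formats embed the resolved configuration (CSV as ``#`` comment
    lines) so the numbers are auditable; no timestamps, so identical inputs
    give byte-identical files.
    """
    if fmt == "json":
        payload = {"config": config.to_dict(),
                   "rows": [dataclasses.asdict(r) for r in rows]}
        atomic_write_text(json.dumps(payload, indent=2) + "\n", path)
    elif fmt == "csv":
        header = "".join(f"# {k}={v}\n"
                         for k, v in sorted(config.to_dict().items()))
        df = pd.DataFrame([dataclasses.asdict(r) for r in rows])
        atomic_write_text(header + df.to_csv(index=False,
                                             ), path)
    else:
        raise ValueError("fmt must be 'csv' or 'json'")


def read_report(path) -> pd.DataFrame:
    """Read back a CSV report written by :func:`write_report`."""
    return pd.read_csv(path, comment="#")
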