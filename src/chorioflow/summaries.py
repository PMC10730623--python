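"""Case-level anatomic and hemodynamic summaries.

For each simulated case the hemodynamic variables — endothelial shear
stress over wall cells, velocity magnitude over capillary fluid cells, and
the arteriole-inlet pressure drop ``P^Art - p`` over fluid cells — are
summarized by arithmetic mean (Ave), geometric mean (Mean), and median
(Med), mirroring the donor-case tables; cross-case values are combined by
area-weighted averaging.  The packaged reference tables carry the eight
donor cases' anatomic and hemodynamic entries.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

from .engine import BoundaryConfig, MacroFields
from .geometry import OccupancyGrid
from .units import MMHG_TO_PA
from .wallstress import WallStressResult

__all__ = [
    "SummaryStats",
    "CaseSummary",
    "FixtureTables",
    "summary_stats",
    "summarize_case",
    "weighted_average",
    "density_response_curve",
    "load_fixture_tables",
]

_TABLE_SHA256 = {
    "table1_anatomy.csv":
        "36407c5a1d71fc73d50cebb43f189d4bca7e3aacd4ecc8007211e6e9209ac746",
    "table2_hemodynamics.csv":
        "6778ddddd5b1b82617a968e0555b241d02d9fdb1ccd7273da3d9065aaa2afc15",
}


@dataclass(frozen=True)
class SummaryStats:
    """Arithmetic mean, geometric mean and median of one variable.

    The geometric mean is taken over strictly positive samples only;
    ``n_excluded`` counts the zeros/negatives left out.
    """

    ave: float
    mean: float    # geometric
    med: float
    n: int
    n_excluded: int


def summary_stats(values: np.ndarray) -> SummaryStats:
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size == 0:
        raise ValueError("no samples")
    pos = v[v > 0]
    gm = float(stats.gmean(pos)) if pos.size else float("nan")
    return SummaryStats(ave=float(v.mean()), mean=gm,
                        med=float(np.median(v)), n=int(v.size),
                        n_excluded=int(v.size - pos.size))


@dataclass(frozen=True)
class CaseSummary:
    """Hemodynamic summary of one simulated case."""

    ess_pa: SummaryStats
    velocity_mm_s: SummaryStats
    pressure_drop_mmhg: SummaryStats

    def as_row(self) -> dict[str, float]:
        out = {}
        for name, s in (("ess_pa", self.ess_pa),
                        ("vel_mm_s", self.velocity_mm_s),
                        ("dp_mmhg", self.pressure_drop_mmhg)):
            out[f"{name}_ave"] = s.ave
            out[f"{name}_mean"] = s.mean
            out[f"{name}_med"] = s.med
        return out


def summarize_case(macro: MacroFields, grid: OccupancyGrid,
                   wall: WallStressResult,
                   bc: BoundaryConfig | None = None) -> CaseSummary:
    """Summarize a converged case.

    ESS statistics run over wall cells with defined normals; velocity
    magnitude over capillary-layer fluid cells; the pressure drop
    ``P^Art - p`` (mmHg) over all fluid cells, referenced to the
    configured arteriole inlet pressure.
    """
    bc = bc or BoundaryConfig()
    ess = wall.ess_magnitude
    ess = ess[np.isfinite(ess)]
    if ess.size == 0:
        raise ValueError("no wall cells with defined normals")
    zsl = grid.capillary_layers()
    fluid = grid.P[:, :, zsl] < 1.0
    if not fluid.any():
        raise ValueError("no fluid cells in the capillary layers")
    speed = macro.speed[:, :, zsl][fluid] * 1e3          # mm/s
    p = macro.pressure
    fl3 = (grid.P < 1.0)
    dp = (bc.p_art_mmhg * MMHG_TO_PA - p[fl3]) / MMHG_TO_PA
    return CaseSummary(ess_pa=summary_stats(ess),
                       velocity_mm_s=summary_stats(speed),
                       pressure_drop_mmhg=summary_stats(dp))


def weighted_average(values, areas) -> float:
    """Area-weighted cross-case average: sum(a_k v_k) / sum(a_k)."""
    v = np.asarray(values, dtype=float)
    a = np.asarray(areas, dtype=float)
    if v.shape != a.shape:
        raise ValueError("values and areas must have equal length")
    if (a <= 0).any():
        raise ValueError("areas must be positive")
    return float((a * v).sum() / a.sum())


def density_response_curve(runs) -> pd.DataFrame:
    """Relate capillary density to mean velocity and mean ESS.

    ``runs`` is an iterable of ``(label, density_pct, mean_velocity,
    mean_ess)``; returns the table sorted by density with Spearman rank
    correlations attached as ``DataFrame.attrs['spearman_velocity']`` /
    ``['spearman_ess']`` (nan when a response is constant).
    """
    rows = list(runs)
    if len(rows) < 3:
        raise ValueError("need at least 3 permutation runs")
    df = pd.DataFrame(rows, columns=["label", "density_pct",
                                     "mean_velocity", "mean_ess"])
    df = df.sort_values("density_pct").reset_index(drop=True)
    for col, key in (("mean_velocity", "spearman_velocity"),
                     ("mean_ess", "spearman_ess")):
        if df[col].nunique() == 1:
            df.attrs[key] = float("nan")
        else:
            df.attrs[key] = float(
                stats.spearmanr(df["density_pct"], df[col]).statistic)
    return df


@dataclass(frozen=True)
class FixtureTables:
    """Packaged donor-case reference tables (anatomy and hemodynamics)."""

    anatomy: pd.DataFrame
    hemodynamics: pd.DataFrame

    @property
    def case_hemodynamics(self) -> pd.DataFrame:
        """Hemodynamics rows for the eight cases (weighted row dropped)."""
        df = self.hemodynamics
        return df[df["case"] != "weighted_average"].reset_index(drop=True)


def load_fixture_tables() -> FixtureTables:
    """Load the packaged per-case tables, verifying their checksums."""
    frames = {}
    for fname in _TABLE_SHA256:
        ref = resources.files("chorioflow.data") / fname
        raw = ref.read_bytes()
        digest = hashlib.sha256(raw).hexdigest()
        if digest != _TABLE_SHA256[fname]:
            raise RuntimeError(f"checksum mismatch for packaged {fname}")
        from io import BytesIO
        frames[fname] = pd.read_csv(BytesIO(raw), dtype={"case": str})
    return FixtureTables(anatomy=frames["table1_anatomy.csv"],
                         hemodynamics=frames["table2_hemodynamics.csv"])
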