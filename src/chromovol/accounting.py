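"""DNA packing density, standard curves and cylinder-shell accounting.

The geometric bookkeeping behind the periphery-compartment estimate:

* packing density — DNA content per unit chromosome volume (Mb/um^3);
* a through-origin standard curve of DNA content vs chromosome volume,
  used to estimate the DNA content of an object from its volume;
* a cylinder model of the chromosome complement, V = pi r^2 h, whose
  shell algebra converts a periphery volume into a uniform shell
  thickness t (and back), and gives the volume fraction held by a shell
  of thickness t on a cylinder of radius r: 1 - ((r - t)/r)^2;
* volume/surface accounting between mitotic stages, with every percent
  difference carrying an explicit base;
* loop arithmetic converting a packing density and a radial-loop size
  into loops per um^3 and per cell.
"""

from __future__ import annotations

import importlib.resources
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

NM_PER_UM = 1000.0


# ---------------------------------------------------------------------------
# genome bookkeeping
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomeInfo:
    """DNA content of a dividing (4C) cell plus per-chromosome values (Mb)."""

    total_dna_mb: float = 12344.0
    per_chromosome_mb: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.total_dna_mb <= 0:
            raise ValueError("total_dna_mb must be > 0")
        for k, v in self.per_chromosome_mb.items():
            if v <= 0:
                raise ValueError(f"chromosome {k}: DNA content must be > 0")
            if v > self.total_dna_mb:
                raise ValueError(f"chromosome {k}: entry exceeds the total")

    @staticmethod
    def human_female_diploid() -> "GenomeInfo":
        """GRCh38 chromosome lengths (Ensembl); 46,XX complement."""
        ref = importlib.resources.files("chromovol.data") / "human_chromosome_mb.csv"
        with importlib.resources.as_file(ref) as path:
            table = pd.read_csv(path)
        per = dict(zip(table["chromosome"], table["length_mb"]))
        return GenomeInfo(total_dna_mb=12344.0, per_chromosome_mb=per)


def packing_density(total_dna_mb: float, total_volume_um3: float) -> float:
    """DNA compaction ratio in Mb/um^3."""
    if total_dna_mb <= 0 or total_volume_um3 <= 0:
        raise ValueError("DNA content and volume must both be > 0")
    return total_dna_mb / total_volume_um3


# ---------------------------------------------------------------------------
# standard curve
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StandardCurve:
    """Linear DNA-content-vs-volume calibration (Mb per um^3).

    Fit through the origin by default: a zero-volume chromosome carries
    zero DNA, and only a slope is physically meaningful.
    """

    slope_mb_per_um3: float
    intercept_mb: float = 0.0
    r_squared: float = 1.0
    points: tuple = ()

    def predict(self, volume_um3: float) -> float:
        if volume_um3 < 0:
            raise ValueError("volume must be >= 0")
        return self.slope_mb_per_um3 * volume_um3 + self.intercept_mb


def fit_standard_curve(points, through_origin: bool = True) -> StandardCurve:
    """Least-squares line through (volume_um3, dna_mb) points.

    Through the origin the slope is sum(xy)/sum(x^2); otherwise an
    ordinary two-parameter fit. R^2 is reported against the mean (or
    against zero for the origin-constrained fit).
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be (n, 2): (volume_um3, dna_mb)")
    x, y = pts[:, 0], pts[:, 1]
    if through_origin:
        if len(pts) < 1 or np.sum(x**2) == 0:
            raise ValueError("need at least one point with nonzero volume")
        slope = float(np.sum(x * y) / np.sum(x**2))
        intercept = 0.0
        ss_res = float(np.sum((y - slope * x) ** 2))
        ss_tot = float(np.sum(y**2))
    else:
        if len(pts) < 2 or np.var(x) == 0:
            raise ValueError("need >= 2 points with nonzero volume variance")
        slope_f, intercept_f = np.polyfit(x, y, 1)
        slope, intercept = float(slope_f), float(intercept_f)
        ss_res = float(np.sum((y - (slope * x + intercept)) ** 2))
        ss_tot = float(np.sum((y - y.mean()) ** 2))
    if slope <= 0:
        raise ValueError("fitted slope is non-positive; data are not a packing curve")
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return StandardCurve(
        slope_mb_per_um3=slope,
        intercept_mb=intercept,
        r_squared=r2,
        points=tuple(map(tuple, pts)),
    )


def estimate_dna(volume_um3: float, curve: StandardCurve, chromatid_pair: bool = False):
    """DNA content (Mb) of an object from its volume via a standard curve.

    For an object that is a paired-chromatid unit, the per-chromatid
    value is half the pair total; returns (total_mb, per_chromatid_mb or
    None).
    """
    total = curve.predict(volume_um3)
    return (total, total / 2.0) if chromatid_pair else (total, None)


# ---------------------------------------------------------------------------
# cylinder-shell model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CylinderShellModel:
    """The chromosome complement as one equivalent cylinder plus a shell.

    The complement's summed chromatin volume V and mean diameter 2r imply
    a total length h = V / (pi r^2); a uniform shell of thickness t on
    that cylinder has volume pi h ((r + t)^2 - r^2). The algebra is
    exact in both directions.
    """

    core_volume_um3: float
    mean_diameter_um: float

    def __post_init__(self) -> None:
        if self.core_volume_um3 <= 0 or self.mean_diameter_um <= 0:
            raise ValueError("core volume and diameter must be > 0")

    @property
    def radius_um(self) -> float:
        return self.mean_diameter_um / 2.0

    @property
    def implied_total_length_um(self) -> float:
        return self.core_volume_um3 / (math.pi * self.radius_um**2)

    def shell_volume_from_thickness(self, thickness_nm: float) -> float:
        if thickness_nm < 0:
            raise ValueError("thickness must be >= 0")
        t = thickness_nm / NM_PER_UM
        r, h = self.radius_um, self.implied_total_length_um
        return math.pi * h * ((r + t) ** 2 - r**2)

    def shell_thickness_from_volume(self, shell_volume_um3: float) -> float:
        """Thickness t (nm) of the uniform shell holding ``shell_volume``.

        Solves pi h ((r + t)^2 - r^2) = V_shell for the positive root:
        t = sqrt(r^2 + V_shell / (pi h)) - r. Exact closed form.
        """
        if shell_volume_um3 < 0:
            raise ValueError("shell volume must be >= 0")
        r, h = self.radius_um, self.implied_total_length_um
        t_um = math.sqrt(r**2 + shell_volume_um3 / (math.pi * h)) - r
        return t_um * NM_PER_UM


def shell_thickness_from_volume(
    core_volume_um3: float, mean_diameter_um: float, shell_volume_um3: float
) -> float:
    """Uniform-shell thickness (nm) on the equivalent-cylinder complement."""
    model = CylinderShellModel(core_volume_um3, mean_diameter_um)
    return model.shell_thickness_from_volume(shell_volume_um3)


def periphery_fraction(diameter_um: float, thickness_nm: float) -> float:
    """Volume fraction of a cylindrical chromosome held by its surface shell.

    For outer radius r = diameter/2 and shell thickness t:
    fraction = 1 - ((r - t)/r)^2. Strictly increasing in t, decreasing
    in r; a thin shell on a thin cylinder holds a large share because
    the cross-section scales with r^2.
    """
    r_nm = diameter_um / 2.0 * NM_PER_UM
    if thickness_nm < 0 or thickness_nm >= r_nm:
        raise ValueError("need 0 <= thickness < radius")
    return 1.0 - ((r_nm - thickness_nm) / r_nm) ** 2


def chromatin_fraction(diameter_um: float, thickness_nm: float) -> float:
    """Complement of :func:`periphery_fraction`: the core (chromatin) share."""
    return 1.0 - periphery_fraction(diameter_um, thickness_nm)


# ---------------------------------------------------------------------------
# volume accounting and percent comparisons
# ---------------------------------------------------------------------------

def percent_difference(a: float, b: float) -> float:
    """100 * (a - b) / max(a, b): percent difference on the larger base."""
    if a == b:
        return 0.0
    return 100.0 * abs(a - b) / max(a, b)


def volume_accounting(
    prophase_volume_um3: float,
    nucleolus_volume_um3: float,
    metaphase_volume_um3: float,
) -> dict:
    """Does prophase chromatin + nucleolus account for the metaphase volume?

    Returns the sum, its gap to the metaphase volume, and percent
    differences, each labeled with its base (the larger quantity).
    """
    if min(prophase_volume_um3, nucleolus_volume_um3, metaphase_volume_um3) < 0:
        raise ValueError("volumes must be >= 0")
    total = prophase_volume_um3 + nucleolus_volume_um3
    return {
        "prophase_volume_um3": prophase_volume_um3,
        "nucleolus_volume_um3": nucleolus_volume_um3,
        "prophase_plus_nucleolus_um3": total,
        "metaphase_volume_um3": metaphase_volume_um3,
        "gap_um3": metaphase_volume_um3 - total,
        "metaphase_vs_prophase_pct": percent_difference(metaphase_volume_um3, prophase_volume_um3),
        "metaphase_vs_prophase_base": "metaphase" if metaphase_volume_um3 >= prophase_volume_um3 else "prophase",
        "metaphase_vs_sum_pct": percent_difference(metaphase_volume_um3, total),
        "metaphase_vs_sum_base": "metaphase" if metaphase_volume_um3 >= total else "prophase+nucleolus",
    }


def surface_reduction(surface_a_um2: float, surface_b_um2: float) -> float:
    """Percent surface-area reduction from a to b, on the larger base."""
    if surface_a_um2 <= 0 or surface_b_um2 <= 0:
        raise ValueError("surface areas must be > 0")
    return percent_difference(surface_a_um2, surface_b_um2)


def loop_arithmetic(
    packing_mb_per_um3: float,
    loop_size_kb: float,
    chromatin_volume_um3: float,
) -> dict:
    """Radial-loop counts implied by a packing density and loop size.

    loops/um^3 = packing (Mb/um^3) * 1000 (kb/Mb) / loop size (kb);
    total = loops/um^3 * chromatin volume. The inputs used are echoed in
    the result, since published headline counts depend on which packing
    density and volume are taken as the base.
    """
    if min(packing_mb_per_um3, loop_size_kb, chromatin_volume_um3) <= 0:
        raise ValueError("all loop-arithmetic inputs must be > 0")
    per_um3 = packing_mb_per_um3 * 1000.0 / loop_size_kb
    return {
        "packing_mb_per_um3": packing_mb_per_um3,
        "loop_size_kb": loop_size_kb,
        "chromatin_volume_um3": chromatin_volume_um3,
        "loops_per_um3": per_um3,
        "total_loops": per_um3 * chromatin_volume_um3,
    }
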