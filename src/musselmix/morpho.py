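"""Shell morphology, morphotype-genotype concordance and substrate ecology.

The "dark strip" character: on the inner shell surface, the dark
prismatic layer may run under the ligament as a strip.  With l the
umbo-to-posterior-ligament distance and a the umbo-to-anterior-strip
distance (a = 0 when the strip is unbroken, a = l when it is absent), the
index Z = a/l summarises the character; Z = 0 exactly defines the
T-morphotype (typical of *M. trossulus*), any Z > 0 the E-morphotype.

Quadrat densities: bottom samples use a 16 x 16 cm core frame; algal
samples count mussels on a weighed tuft from a 50 x 50 cm frame and scale
by the total-to-tuft algae weight ratio.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["z_index", "morphotype", "annotate_shells", "concordance",
           "density_bottom", "density_algae", "substrate_contrast",
           "DensityEstimate"]


@dataclass
class DensityEstimate:
    substrate: str
    per_m2: float
    meta: dict

    def __post_init__(self) -> None:
        if self.per_m2 < 0:
            raise ValueError("density cannot be negative")


def z_index(a: float, l: float) -> float:
    """Relative anterior gap of the dark strip, Z = a/l in [0, 1]."""
    if l <= 0:
        raise ValueError(f"ligament distance l must be positive, got {l}")
    if not 0 <= a <= l:
        raise ValueError(f"need 0 <= a <= l, got a={a}, l={l}")
    return a / l


def morphotype(z: float) -> str:
    """T-morphotype iff Z = 0 exactly (unbroken strip); E otherwise."""
    if not 0 <= z <= 1:
        raise ValueError(f"Z must lie in [0, 1], got {z}")
    return "T" if z == 0 else "E"


def annotate_shells(shells: pd.DataFrame) -> pd.DataFrame:
    """Append ``z`` and ``morphotype`` columns to a shell-measurement table
    with columns ``L``, ``l``, ``a`` (mm)."""
    out = shells.copy()
    out["z"] = [z_index(a, l) for a, l in zip(out["a"], out["l"])]
    out["morphotype"] = [morphotype(z) for z in out["z"]]
    return out


def concordance(classes: pd.Series, morphotypes: pd.Series,
                include_hybrids: bool = False) -> pd.DataFrame:
    """Genotype-morphotype concordance for the two purebred classes.

    Efficiency: fraction of a genetic class bearing its expected
    morphotype (MT -> T, ME -> E).  Accuracy: fraction of a morphotype
    whose bearers belong to the matching genetic class.  Hybrids are
    excluded by default; with ``include_hybrids=True`` their morphotype
    split is reported as an extra row (no expected morphotype, so no
    efficiency).  Returns a tidy DataFrame plus an ``overall`` attribute
    in ``df.attrs`` (mean efficiency x mean accuracy over ME and MT).
    """
    df = pd.DataFrame({"cls": classes, "morph": morphotypes}).dropna()
    expected = {"MT": "T", "ME": "E"}
    rows = []
    effs, accs = [], []
    for cls, exp_m in expected.items():
        members = df[df["cls"] == cls]
        carriers = df[(df["morph"] == exp_m) & (df["cls"] != "HYBRID")] \
            if not include_hybrids else df[df["morph"] == exp_m]
        if len(members) == 0:
            warnings.warn(f"no individuals in genetic class {cls}; omitted")
            continue
        eff = float((members["morph"] == exp_m).mean())
        acc = float((carriers["cls"] == cls).mean()) if len(carriers) else np.nan
        rows.append({"class": cls, "expected_morph": exp_m, "n": len(members),
                     "efficiency": eff, "accuracy": acc})
        effs.append(eff)
        if not np.isnan(acc):
            accs.append(acc)
    if include_hybrids and (df["cls"] == "HYBRID").any():
        hyb = df[df["cls"] == "HYBRID"]
        rows.append({"class": "HYBRID", "expected_morph": None, "n": len(hyb),
                     "efficiency": np.nan,
                     "accuracy": float((hyb["morph"] == "T").mean())})
    out = pd.DataFrame(rows)
    out.attrs["overall"] = float(np.mean(effs) * np.mean(accs)) if effs and accs else np.nan
    return out


def density_bottom(count: int, core_side: float = 0.16) -> DensityEstimate:
    """Mussels per square metre from a bottom core-frame count
    (default 16 x 16 cm frame)."""
    if count < 0:
        raise ValueError("count must be >= 0")
    area = core_side ** 2
    return DensityEstimate("bottom", count / area,
                           {"count": count, "core_side_m": core_side, "area_m2": area})


def density_algae(tuft_count: int, tuft_weight: float, total_algae_weight: float,
                  frame_area: float = 0.25) -> DensityEstimate:
    """Mussels per square metre on algae: tuft count scaled by the
    total-to-tuft algae weight ratio over the frame area (default 50 x 50
    cm frame = 0.25 m^2)."""
    if tuft_count < 0:
        raise ValueError("count must be >= 0")
    if tuft_weight <= 0:
        raise ValueError("tuft weight must be positive")
    if total_algae_weight < tuft_weight:
        raise ValueError("tuft cannot outweigh the total algae")
    per_m2 = tuft_count * (total_algae_weight / tuft_weight) / frame_area
    return DensityEstimate("algae", per_m2,
                           {"tuft_count": tuft_count, "tuft_weight": tuft_weight,
                            "total_algae_weight": total_algae_weight,
                            "frame_area_m2": frame_area})


def substrate_contrast(records: pd.DataFrame, value: str = "is_t",
                       n_boot: int = 1000, seed: int = 0) -> pd.DataFrame:
    """Per-site algae-minus-bottom frequency difference with a percentile
    bootstrap confidence interval.

    *records* needs columns ``site``, ``substrate`` (algae/bottom) and a
    binary column *value* (e.g. T-morphotype indicator, or MT-class
    indicator of genotyped mussels).  Sites missing either substrate are
    skipped with a warning.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for site, grp in records.groupby("site"):
        a = grp.loc[grp["substrate"] == "algae", value].to_numpy(dtype=float)
        b = grp.loc[grp["substrate"] == "bottom", value].to_numpy(dtype=float)
        if len(a) == 0 or len(b) == 0:
            warnings.warn(f"site {site} lacks one substrate; skipped")
            continue
        diff = a.mean() - b.mean()
        boots = np.empty(n_boot)
        for i in range(n_boot):
            boots[i] = (rng.choice(a, len(a)).mean() - rng.choice(b, len(b)).mean())
        lo, hi = np.percentile(boots, [2.5, 97.5])
        rows.append({"site": site, "n_algae": len(a), "n_bottom": len(b),
                     "freq_algae": a.mean(), "freq_bottom": b.mean(),
                     "difference": diff, "ci_low": lo, "ci_high": hi,
                     "n_boot": n_boot, "seed": seed})
    return pd.DataFrame(rows)
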