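"""Fatty-acid shorthand parsing, class sums and replicate statistics.

Fatty acids are named by the ``C:Dn-x`` shorthand (carbon count, number
of double bonds, and the omega position of the first double bond from
the methyl end).  Saturation classes partition every profile: SFA (no
double bonds), MUFA (one), PUFA (two or more); omega-3 and omega-6 sums
run across saturation classes.  Strain profiles are summarised exactly
as printed tables do -- class totals are plain sums of the member means,
the omega-3/omega-6 ratio is rounded half-away-from-zero to one decimal,
and summary standard errors are propagated as sqrt of summed squared SEs
(reported alongside, never part of the exact-sum checks).

Group comparisons use classical one-way ANOVA with Tukey's HSD post-hoc
test at alpha = 0.05.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from math import sqrt
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InputError

VALID_UNITS = ("percent-of-total-FA", "mg-per-L")

# "18:3n-3", "18:3 n-3", "18:3ω3", "18:3 omega-3" + optional common name.
_SHORTHAND_RE = re.compile(
    r"""^\s*(?P<carbons>\d+):(?P<bonds>\d+)
        (?:\s*(?:n-|ω|omega-?)(?P<omega>\d+))?
        (?:\s+(?P<name>\S.*?))?\s*$""",
    re.VERBOSE,
)


@dataclass(frozen=True)
class FattyAcidName:
    carbons: int
    double_bonds: int
    omega: Optional[int] = None
    common_name: Optional[str] = None

    def __post_init__(self):
        if self.carbons < 4:
            raise InputError(f"implausible carbon count {self.carbons}")
        if self.double_bonds < 0:
            raise InputError("negative double-bond count")
        if (self.omega is None) != (self.double_bonds == 0):
            raise InputError(
                "omega position must be present exactly when double bonds exist"
            )
        if self.omega is not None and self.omega < 1:
            raise InputError("omega position must be >= 1")

    def shorthand(self) -> str:
        core = f"{self.carbons}:{self.double_bonds}"
        if self.omega is not None:
            core += f"n-{self.omega}"
        return core

    @property
    def saturation_class(self) -> str:
        if self.double_bonds == 0:
            return "SFA"
        return "MUFA" if self.double_bonds == 1 else "PUFA"

    @property
    def omega_class(self) -> Optional[str]:
        return None if self.omega is None else f"omega-{self.omega}"


def parse_fa_shorthand(text: str) -> FattyAcidName:
    """Parse ``"18:3n-3 α-Linolenic"``-style labels.

    Accepts the ``n-x``, ``ωx`` and ``omega-x`` spellings; the canonical
    rendering is always ``n-x``.  An omega designation on a saturated
    acid (or a missing one on an unsaturated acid) is a parse error.
    """
    m = _SHORTHAND_RE.match(text)
    if not m:
        raise InputError(f"cannot parse fatty-acid shorthand {text!r}")
    carbons = int(m.group("carbons"))
    bonds = int(m.group("bonds"))
    omega = int(m.group("omega")) if m.group("omega") else None
    if bonds == 0 and omega is not None:
        raise InputError(f"saturated acid {text!r} cannot carry an omega position")
    if bonds > 0 and omega is None:
        raise InputError(f"unsaturated acid {text!r} lacks an omega position")
    return FattyAcidName(
        carbons=carbons,
        double_bonds=bonds,
        omega=omega,
        common_name=m.group("name"),
    )


def classify_fa(fa: FattyAcidName) -> tuple[str, Optional[str]]:
    """(saturation class, omega class) labels for one fatty acid."""
    return fa.saturation_class, fa.omega_class


@dataclass(frozen=True)
class FattyAcidMeasurement:
    strain: str
    fa: FattyAcidName
    mean: float
    se: float
    unit: str
    replicates: Optional[tuple[float, ...]] = None

    def __post_init__(self):
        if self.unit not in VALID_UNITS:
            raise InputError(f"unknown unit {self.unit!r}")
        if self.mean < 0 or self.se < 0:
            raise InputError("mean and SE must be non-negative")
        if self.replicates is not None:
            if abs(self.mean - float(np.mean(self.replicates))) > 0.005 + 1e-9:
                raise InputError(
                    "replicate mean disagrees with the reported mean beyond "
                    "reporting precision"
                )


@dataclass(frozen=True)
class FaSummary:
    """Per-strain class totals in the unit of the input measurements."""

    strain: str
    unit: str
    sfa: float
    mufa: float
    pufa: float
    omega3: float
    omega6: float
    omega_ratio: Optional[float]  # omega3/omega6, half-away-from-zero, 1 dp
    se: dict[str, float] = field(default_factory=dict, compare=False)

    @property
    def total(self) -> float:
        return self.sfa + self.mufa + self.pufa

    def to_dict(self) -> dict:
        # round(x, 10) strips float-summation noise without touching the
        # reporting precision of the inputs (2 decimals).
        return {
            "strain": self.strain,
            "unit": self.unit,
            "SFA": round(self.sfa, 10),
            "MUFA": round(self.mufa, 10),
            "PUFA": round(self.pufa, 10),
            "omega3": round(self.omega3, 10),
            "omega6": round(self.omega6, 10),
            "omega_ratio": self.omega_ratio,
            "se": {k: round(v, 10) for k, v in sorted(self.se.items())},
        }


def round_half_away(value: float, decimals: int = 1) -> float:
    """Round half away from zero (the convention of printed ratios)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def summarize_profile(measurements: Sequence[FattyAcidMeasurement]) -> FaSummary:
    """Class sums, omega sums and the omega-3/omega-6 ratio for one strain.

    Totals are exact sums of the member means; SEs of the sums are
    propagated as sqrt of summed squared SEs and reported separately.
    An empty measurement set yields an all-zero summary with the ratio
    flagged undefined (None).
    """
    if not measurements:
        return FaSummary(
            strain="", unit=VALID_UNITS[0], sfa=0.0, mufa=0.0, pufa=0.0,
            omega3=0.0, omega6=0.0, omega_ratio=None,
        )
    units = {m.unit for m in measurements}
    if len(units) > 1:
        raise InputError(f"mixed units in one profile: {sorted(units)}")
    strains = {m.strain for m in measurements}
    if len(strains) > 1:
        raise InputError(f"measurements span several strains: {sorted(strains)}")
    seen: set[str] = set()
    for m in measurements:
        key = m.fa.shorthand()
        if key in seen:
            raise InputError(f"duplicate fatty acid {key} for strain {m.strain}")
        seen.add(key)

    sums = {"SFA": 0.0, "MUFA": 0.0, "PUFA": 0.0, "omega-3": 0.0, "omega-6": 0.0}
    sq = {k: 0.0 for k in sums}
    for m in measurements:
        sat, omega = classify_fa(m.fa)
        sums[sat] += m.mean
        sq[sat] += m.se**2
        if omega in ("omega-3", "omega-6"):
            sums[omega] += m.mean
            sq[omega] += m.se**2
    ratio = (
        round_half_away(sums["omega-3"] / sums["omega-6"], 1)
        if sums["omega-6"] > 0
        else None
    )
    return FaSummary(
        strain=next(iter(strains)),
        unit=next(iter(units)),
        sfa=sums["SFA"],
        mufa=sums["MUFA"],
        pufa=sums["PUFA"],
        omega3=sums["omega-3"],
        omega6=sums["omega-6"],
        omega_ratio=ratio,
        se={k: sqrt(v) for k, v in sq.items()},
    )


# ---------------------------------------------------------------------------
# Table I/O
# ---------------------------------------------------------------------------

def read_fa_table(path_or_df: str | Path | pd.DataFrame) -> list[FattyAcidMeasurement]:
    """Read a long-format CSV (strain, fatty_acid, mean, se, unit)."""
    df = (
        path_or_df
        if isinstance(path_or_df, pd.DataFrame)
        else pd.read_csv(path_or_df)
    )
    required = {"strain", "fatty_acid", "mean", "se", "unit"}
    missing = required - set(df.columns)
    if missing:
        raise InputError(f"fatty-acid table lacks columns {sorted(missing)}")
    return [
        FattyAcidMeasurement(
            strain=str(row.strain),
            fa=parse_fa_shorthand(str(row.fatty_acid)),
            mean=float(row.mean),
            se=float(row.se),
            unit=str(row.unit),
        )
        for row in df.itertuples()
    ]


def load_packaged_table(name: str) -> list[FattyAcidMeasurement]:
    """Load a table shipped with the package.

    ``name`` is ``"table2_percent"`` (% of total FAs) or
    ``"table3_mg_per_l"`` (volumetric yields, mg per litre).
    """
    ref = resources.files("phycodelim.data").joinpath(f"{name}.csv")
    with resources.as_file(ref) as path:
        return read_fa_table(path)


def load_printed_summary_rows() -> pd.DataFrame:
    """Printed summary rows (class totals, omega sums, ratios) as shipped."""
    ref = resources.files("phycodelim.data").joinpath("printed_summary_rows.csv")
    with resources.as_file(ref) as path:
        return pd.read_csv(path)


def summarize_table(
    measurements: Iterable[FattyAcidMeasurement],
) -> dict[str, FaSummary]:
    """Per-strain summaries for a whole table, in first-seen strain order."""
    by_strain: dict[str, list[FattyAcidMeasurement]] = {}
    for m in measurements:
        by_strain.setdefault(m.strain, []).append(m)
    return {s: summarize_profile(ms) for s, ms in by_strain.items()}


# ---------------------------------------------------------------------------
# ANOVA + Tukey
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TukeyPair:
    group_a: str
    group_b: str
    p_adj: float
    significant: bool


@dataclass(frozen=True)
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p: float
    alpha: float
    tukey: tuple[TukeyPair, ...]

    def to_dict(self) -> dict:
        return {
            "F": self.F,
            "df_between": self.df_between,
            "df_within": self.df_within,
            "p": self.p,
            "alpha": self.alpha,
            "tukey": [
                {
                    "group_a": t.group_a,
                    "group_b": t.group_b,
                    "p_adj": t.p_adj,
                    "significant": t.significant,
                }
                for t in self.tukey
            ],
        }


def anova_oneway(
    groups: dict[str, Sequence[float]], alpha: float = 0.05
) -> AnovaResult:
    """Classical one-way ANOVA with Tukey HSD pairwise comparisons.

    Groups with equal means give F = 0 (including the all-identical
    degenerate case where the usual F ratio is 0/0).  Every group needs
    at least two replicates.
    """
    if len(groups) < 2:
        raise InputError("ANOVA needs at least two groups")
    names = list(groups)
    arrays = [np.asarray(groups[name], dtype=float) for name in names]
    for name, arr in zip(names, arrays):
        if arr.size < 2:
            raise InputError(f"group {name!r} has fewer than two replicates")
    n_total = sum(a.size for a in arrays)
    df_between = len(arrays) - 1
    df_within = n_total - len(arrays)

    grand = np.concatenate(arrays).mean()
    ss_between = sum(a.size * (a.mean() - grand) ** 2 for a in arrays)
    if ss_between <= 1e-12:
        f_stat, p_value = 0.0, 1.0
    else:
        f_stat, p_value = stats.f_oneway(*arrays)

    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    if ss_within <= 1e-12 and ss_between <= 1e-12:
        pairs = tuple(
            TukeyPair(names[i], names[j], 1.0, False)
            for i in range(len(names))
            for j in range(i + 1, len(names))
        )
    else:
        hsd = stats.tukey_hsd(*arrays)
        pairs = tuple(
            TukeyPair(
                names[i],
                names[j],
                float(hsd.pvalue[i, j]),
                bool(hsd.pvalue[i, j] < alpha),
            )
            for i in range(len(names))
            for j in range(i + 1, len(names))
        )
    return AnovaResult(
        F=float(f_stat),
        df_between=df_between,
        df_within=df_within,
        p=float(p_value),
        alpha=alpha,
        tukey=pairs,
    )
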