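"""Energy and nitrogen balance from digestibility trials and indirect calorimetry.

Implements the classical factorial bookkeeping for a growing pig housed in a
respiration chamber: apparent total tract digestibility, nitrogen retention,
digestible and metabolizable energy, heat production by the Brouwer equation,
and the partition of metabolizable energy intake (MEI) into total heat
production (THP) and retained energy (RE), with RE further split into protein
deposition (PD, from nitrogen retention) and lipid deposition (LD).

Internal convention: energies in kJ, masses in kg dry matter (DM); MJ and
percentages appear only at the I/O boundary.  Rates are scaled by metabolic
body weight BW^0.6 so that every pig is expressed on the kJ/kg BW^0.6/d scale.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "BrouwerCoefficients",
    "DietFormulation",
    "BalanceRecord",
    "GasTrace",
    "EnergyPartition",
    "TraceSummary",
    "attd",
    "nitrogen_retention",
    "net_protein_availability",
    "de_me_values",
    "heat_production",
    "summarize_trace",
    "partition",
    "metabolic_weight",
]

#: g protein per g nitrogen.
N_TO_PROTEIN = 6.25
#: combustion energy of body protein, kJ/g.
PROTEIN_ENERGY = 23.86
#: combustion energy of methane, kJ/L, used when methane energy is not measured.
CH4_ENERGY_PER_L = 39.54

MINUTES_PER_DAY = 1440.0


@dataclass(frozen=True)
class BrouwerCoefficients:
    """Coefficients of the Brouwer heat-production equation (kJ/L, kJ/g).

    HP = c_o2*O2 + c_co2*CO2 + c_ch4*CH4 + c_un*urinary N, with gas volumes
    in L/d and urinary nitrogen in g/d.
    """

    c_o2: float = 16.18
    c_co2: float = 5.02
    c_ch4: float = -2.17
    c_un: float = -5.99
    n_to_protein: float = N_TO_PROTEIN
    protein_energy: float = PROTEIN_ENERGY


DEFAULT_BROUWER = BrouwerCoefficients()


@dataclass
class DietFormulation:
    """One diet: ingredient inclusion (% as-fed) and analyzed nutrient levels.

    ``dm`` is a fraction; ``ash``..``cp`` are % as-fed; ``ge`` is MJ/kg as-fed.
    Nutrient densities per kg DM are the as-fed values divided by ``dm``.
    """

    id: str
    ingredient_pct: Mapping[str, float] = field(default_factory=dict)
    dm: float = 1.0
    ash: float = 0.0
    ee: float = 0.0
    ndf: float = 0.0
    adf: float = 0.0
    cp: float = 0.0
    ge: float = 0.0

    def __post_init__(self) -> None:
        if self.ingredient_pct:
            total = sum(self.ingredient_pct.values())
            if abs(total - 100.0) > 0.01:
                raise ValueError(
                    f"diet {self.id}: ingredient percentages sum to {total:.3f}, not 100"
                )
        if not 0.0 < self.dm <= 1.0:
            raise ValueError(f"diet {self.id}: dm={self.dm} must be a fraction in (0, 1]")
        for name in ("ash", "ee", "ndf", "adf", "cp"):
            v = getattr(self, name)
            if not 0.0 <= v <= 100.0:
                raise ValueError(f"diet {self.id}: {name}={v} outside [0, 100] %")
        if self.ge < 0:
            raise ValueError(f"diet {self.id}: ge={self.ge} must be >= 0")

    @property
    def ge_dm(self) -> float:
        """Gross energy density, MJ/kg DM."""
        return self.ge / self.dm

    def nutrient_dm(self, name: str) -> float:
        """Analyzed nutrient level on the DM basis (% of DM)."""
        return getattr(self, name) / self.dm


@dataclass
class BalanceRecord:
    """One pig-period of intake/output masses, energies, nitrogen and weights.

    Energies in MJ/d, nitrogen in g/d, ``dmi`` in kg DM/d, weights in kg.
    ``ch4_energy`` may be supplied directly; otherwise it can be derived from
    trace methane volumes with :data:`CH4_ENERGY_PER_L`.
    """

    pig_id: str
    diet_id: str
    dmi: float
    ge_intake: float
    fecal_ge: float
    urinary_ge: float
    ch4_energy: float
    n_intake: float
    fecal_n: float
    urinary_n: float
    bw_start: float
    bw_end: float

    def __post_init__(self) -> None:
        for name in ("dmi", "ge_intake", "fecal_ge", "urinary_ge", "ch4_energy",
                     "n_intake", "fecal_n", "urinary_n"):
            if getattr(self, name) < 0:
                raise ValueError(f"{self.pig_id}: {name} must be >= 0")
        if self.bw_start <= 0 or self.bw_end <= 0:
            raise ValueError(f"{self.pig_id}: body weights must be > 0")
        if self.fecal_ge > self.ge_intake:
            raise ValueError(
                f"{self.pig_id}: fecal GE {self.fecal_ge} exceeds GE intake {self.ge_intake}"
            )

    @property
    def mean_bw(self) -> float:
        """Period body weight: arithmetic mean of start and end weights."""
        return 0.5 * (self.bw_start + self.bw_end)


@dataclass
class GasTrace:
    """Chamber gas-exchange series sampled at a fixed interval (default 5 min).

    ``o2``, ``co2``, ``ch4`` are volumes (L) consumed/produced per interval;
    ``fed`` flags whether the pig was in the fed or the fasted state.  Times
    are minutes from the start of the trace and must be strictly increasing.
    """

    pig_id: str
    time_min: np.ndarray
    o2: np.ndarray
    co2: np.ndarray
    ch4: np.ndarray
    fed: np.ndarray
    interval: float = 5.0

    def __post_init__(self) -> None:
        self.time_min = np.asarray(self.time_min, dtype=float)
        self.o2 = np.asarray(self.o2, dtype=float)
        self.co2 = np.asarray(self.co2, dtype=float)
        self.ch4 = np.asarray(self.ch4, dtype=float)
        self.fed = np.asarray(self.fed, dtype=bool)
        n = len(self.time_min)
        if not all(len(a) == n for a in (self.o2, self.co2, self.ch4, self.fed)):
            raise ValueError(f"{self.pig_id}: trace channels have unequal lengths")
        if n > 1 and not np.all(np.diff(self.time_min) > 0):
            raise ValueError(f"{self.pig_id}: timestamps must be strictly increasing")
        if self.interval <= 0:
            raise ValueError(f"{self.pig_id}: interval must be > 0")
        for name in ("o2", "co2", "ch4"):
            if np.any(getattr(self, name) < 0):
                raise ValueError(f"{self.pig_id}: {name} volumes must be >= 0")

    def __len__(self) -> int:
        return len(self.time_min)


@dataclass
class TraceSummary:
    """Daily heat-production rates from a gas trace, kJ/d.

    ``fhp`` is ``None`` when the trace contains no fasted samples; the caller
    must then supply fasting heat production externally.
    """

    thp: float
    fhp: float | None
    n_fed: int
    n_fasted: int


@dataclass
class EnergyPartition:
    """Energy partition of one pig-period on the kJ/kg BW^0.6/d scale.

    Satisfies the accounting identities mei = thp + re, hi = thp - fhp,
    re = pd + ld and pd_free_ne = (mei - hi) - pd by construction.
    Densities are MJ/kg DM.
    """

    pig_id: str
    diet_id: str
    mei: float
    thp: float
    fhp: float
    hi: float
    re: float
    pd: float
    ld: float
    pd_free_ne: float
    ne_density: float
    me_density: float
    de_density: float
    metabolic_bw: float


def metabolic_weight(bw: float) -> float:
    """Metabolic body weight BW^0.6 (kg^0.6) used to scale energy rates."""
    if bw <= 0:
        raise ValueError(f"body weight must be > 0, got {bw}")
    return bw ** 0.6


def attd(intake: float, fecal: float) -> float:
    """Apparent total tract digestibility, (intake - fecal)/intake.

    Returns a fraction; tables conventionally print it as a percentage.  A
    fecal output exceeding intake yields a negative coefficient which is
    flagged with a warning but never clamped, preserving auditability of
    suspect records.
    """
    if intake <= 0:
        raise ValueError(f"intake must be > 0, got {intake}")
    if fecal < 0:
        raise ValueError(f"fecal output must be >= 0, got {fecal}")
    if fecal > intake:
        warnings.warn(
            f"fecal output {fecal} exceeds intake {intake}: negative digestibility",
            stacklevel=2,
        )
    return (intake - fecal) / intake


def nitrogen_retention(n_intake: float, fecal_n: float, urinary_n: float) -> float:
    """Nitrogen retention, g/d: intake minus fecal and urinary losses.

    May be negative for catabolic states; no clamping is applied.
    """
    for name, v in (("n_intake", n_intake), ("fecal_n", fecal_n), ("urinary_n", urinary_n)):
        if v < 0:
            raise ValueError(f"{name} must be >= 0, got {v}")
    return n_intake - fecal_n - urinary_n


def net_protein_availability(n_intake: float, fecal_n: float, urinary_n: float) -> float:
    """Nitrogen retention as a fraction of nitrogen intake."""
    if n_intake <= 0:
        raise ValueError(f"n_intake must be > 0, got {n_intake}")
    return nitrogen_retention(n_intake, fecal_n, urinary_n) / n_intake


def de_me_values(rec: BalanceRecord, per_kg_dm: bool = False) -> tuple[float, float]:
    """Digestible and metabolizable energy of one record.

    DE = GE intake - fecal GE; ME = DE - urinary GE - methane energy, MJ/d.
    With ``per_kg_dm=True`` both are divided by dry-matter intake, giving
    densities in MJ/kg DM.
    """
    de = rec.ge_intake - rec.fecal_ge
    me = de - rec.urinary_ge - rec.ch4_energy
    if per_kg_dm:
        if rec.dmi <= 0:
            raise ValueError(f"{rec.pig_id}: dmi must be > 0 for a density")
        return de / rec.dmi, me / rec.dmi
    return de, me


def heat_production(
    o2: float,
    co2: float,
    ch4: float = 0.0,
    urinary_n: float = 0.0,
    coef: BrouwerCoefficients = DEFAULT_BROUWER,
) -> float:
    """Brouwer heat production, kJ, from gas volumes (L) and urinary N (g)."""
    if o2 < 0 or co2 < 0 or ch4 < 0:
        raise ValueError("gas volumes must be >= 0")
    return coef.c_o2 * o2 + coef.c_co2 * co2 + coef.c_ch4 * ch4 + coef.c_un * urinary_n


def summarize_trace(
    trace: GasTrace,
    urinary_n: float = 0.0,
    coef: BrouwerCoefficients = DEFAULT_BROUWER,
) -> TraceSummary:
    """Total and fasting heat production (daily rates, kJ/d) from a trace.

    Per-interval gas heat is averaged within the fed and fasted windows and
    scaled to a daily rate; the urinary-N term of the Brouwer equation is
    apportioned uniformly over the day (i.e. subtracted once from each daily
    rate), the interval-level distribution of urinary N being unobservable.
    """
    if len(trace) == 0 or not np.any(trace.fed):
        raise ValueError(f"{trace.pig_id}: trace must contain at least one fed sample")
    per_day = MINUTES_PER_DAY / trace.interval
    gas = coef.c_o2 * trace.o2 + coef.c_co2 * trace.co2 + coef.c_ch4 * trace.ch4

    fed = trace.fed
    thp = float(np.mean(gas[fed])) * per_day + coef.c_un * urinary_n
    n_fasted = int(np.count_nonzero(~fed))
    if n_fasted:
        fhp: float | None = float(np.mean(gas[~fed])) * per_day + coef.c_un * urinary_n
    else:
        fhp = None
    return TraceSummary(thp=thp, fhp=fhp, n_fed=int(np.count_nonzero(fed)), n_fasted=n_fasted)


def partition(rec: BalanceRecord, thp: float, fhp: float) -> EnergyPartition:
    """Partition metabolizable energy into heat, protein and lipid deposition.

    ``thp`` and ``fhp`` are daily heat productions in kJ/d (e.g. from
    :func:`summarize_trace`).  All outputs are scaled by the period metabolic
    body weight (mean of start/end BW raised to 0.6).  THP below FHP is
    physiologically suspect and triggers a warning, never a silent fix.
    """
    w = metabolic_weight(rec.mean_bw)
    if thp < fhp:
        warnings.warn(
            f"{rec.pig_id}: THP {thp:.1f} < FHP {fhp:.1f} kJ/d — flagged, not adjusted",
            stacklevel=2,
        )
    de_mj, me_mj = de_me_values(rec)
    mei = me_mj * 1000.0 / w
    thp_s = thp / w
    fhp_s = fhp / w
    hi = thp_s - fhp_s
    ne = mei - hi
    re = mei - thp_s
    nr = nitrogen_retention(rec.n_intake, rec.fecal_n, rec.urinary_n)
    pd = nr * N_TO_PROTEIN * PROTEIN_ENERGY / w
    pd_free_ne = ne - pd
    ld = re - pd

    if rec.dmi > 0:
        de_density = de_mj / rec.dmi
        me_density = me_mj / rec.dmi
        # NE density follows the same MEI -> NE shrinkage as the rates.
        ne_density = me_density * (ne / mei) if mei else float("nan")
    else:
        de_density = me_density = ne_density = float("nan")

    return EnergyPartition(
        pig_id=rec.pig_id,
        diet_id=rec.diet_id,
        mei=mei,
        thp=thp_s,
        fhp=fhp_s,
        hi=hi,
        re=re,
        pd=pd,
        ld=ld,
        pd_free_ne=pd_free_ne,
        ne_density=ne_density,
        me_density=me_density,
        de_density=de_density,
        metabolic_bw=w,
    )
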