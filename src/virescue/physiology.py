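"""Leaf pigment contents and PAM chlorophyll-fluorescence parameters.

Pigments follow the Lichtenthaler-style 80%-acetone equations: absorbances at
663, 646, and 470 nm give chlorophyll a, chlorophyll b, and carotenoid
concentrations in mg/L, which extract volume V (mL) and fresh mass M (g)
convert to mg per g fresh weight:

    ca  = 12.21*OD663 - 2.81*OD646
    cb  = 20.13*OD646 - 5.03*OD663
    cxc = (1000*OD470 - 3.27*ca - 104*cb) / 229
    content [mg/g FW] = concentration * V / (1000 * M)

Saturation-pulse fluorescence parameters use the standard definitions:
Genty's Y(II) = (Fm' - Ft)/Fm'; Kramer's energy partitioning
Y(NPQ) = Ft/Fm' - Ft/Fm and Y(NO) = Ft/Fm (so Y(II)+Y(NPQ)+Y(NO) = 1
identically); puddle-model qP and lake-model qL; Fo' estimated by
Oxborough-Baker when not measured; ETR = 0.5 * 0.84 * PAR * Y(II) with the
usual leaf absorptance 0.84 and PSII fraction 0.5.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "AbsorbanceRecord",
    "PigmentContent",
    "FluorRecord",
    "FluorParams",
    "pigment_content",
    "fvfm",
    "fvfo",
    "saturation_pulse_params",
    "treatment_comparison",
]


@dataclass(frozen=True)
class AbsorbanceRecord:
    """One spectrophotometer reading: ODs plus extract volume and leaf mass."""

    od663: float
    od646: float
    od470: float
    volume_ml: float
    mass_g: float

    def __post_init__(self) -> None:
        for name in ("od663", "od646", "od470"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0")
        if self.volume_ml <= 0 or self.mass_g <= 0:
            raise ValueError("volume and mass must be > 0")


@dataclass(frozen=True)
class PigmentContent:
    """Pigment contents in mg per g fresh weight.

    Negative values (possible near zero from instrument noise) are kept and
    flagged rather than clipped.
    """

    ca: float
    cb: float
    cxc: float

    @property
    def flags(self) -> list[str]:
        return [n for n in ("ca", "cb", "cxc") if getattr(self, n) < 0]


def pigment_content(rec: AbsorbanceRecord) -> PigmentContent:
    """Chlorophyll a/b and carotenoid content (mg/g FW) from absorbances."""
    ca_conc = 12.21 * rec.od663 - 2.81 * rec.od646
    cb_conc = 20.13 * rec.od646 - 5.03 * rec.od663
    cxc_conc = (1000 * rec.od470 - 3.27 * ca_conc - 104 * cb_conc) / 229
    scale = rec.volume_ml / (1000.0 * rec.mass_g)
    return PigmentContent(
        ca=ca_conc * scale, cb=cb_conc * scale, cxc=cxc_conc * scale
    )


def fvfm(fo: float, fm: float) -> float:
    """Maximum quantum yield of PSII, (Fm - Fo)/Fm."""
    if not (fm > fo > 0):
        raise ValueError("require Fm > Fo > 0")
    return (fm - fo) / fm


def fvfo(fo: float, fm: float) -> float:
    """Potential PSII activity, (Fm - Fo)/Fo = FvFm/(1 - FvFm)."""
    if not (fm > fo > 0):
        raise ValueError("require Fm > Fo > 0")
    return (fm - fo) / fo


@dataclass(frozen=True)
class FluorRecord:
    """Dark- and light-adapted fluorescence levels from one saturation pulse.

    ``fo_prime`` may be omitted (estimated by Oxborough-Baker); ``par`` is the
    actinic irradiance in umol m^-2 s^-1 and is only needed for ETR.
    """

    fo: float
    fm: float
    ft: float
    fm_prime: float
    fo_prime: float | None = None
    par: float | None = None

    def __post_init__(self) -> None:
        if not (self.fm > self.fo > 0):
            raise ValueError("require Fm > Fo > 0")
        if not (self.fm_prime >= self.ft > 0):
            raise ValueError("require Fm' >= Ft > 0")
        if self.fo_prime is not None and self.fo_prime <= 0:
            raise ValueError("Fo' must be > 0 when given")


@dataclass(frozen=True)
class FluorParams:
    fvfm: float
    fvfo: float
    yii: float
    npq: float
    qn: float
    qp: float | None
    ql: float | None
    ynpq: float
    yno: float
    etr: float | None
    fo_prime: float
    flags: tuple[str, ...] = ()


def saturation_pulse_params(rec: FluorRecord) -> FluorParams:
    """All standard quenching parameters from one saturation-pulse record.

    The energy partition Y(II) + Y(NPQ) + Y(NO) = 1 holds identically by
    construction.  When Fm' <= Fo', qP and qL are undefined and flagged.
    """
    fv_fm = fvfm(rec.fo, rec.fm)
    fv_fo = fvfo(rec.fo, rec.fm)
    fo_p = rec.fo_prime
    if fo_p is None:
        # Oxborough & Baker estimate from Fo, Fv/Fm, and Fm'
        fo_p = rec.fo / (fv_fm + rec.fo / rec.fm_prime)
    yii = (rec.fm_prime - rec.ft) / rec.fm_prime
    npq = (rec.fm - rec.fm_prime) / rec.fm_prime
    qn = 1 - (rec.fm_prime - fo_p) / (rec.fm - rec.fo)
    ynpq = rec.ft / rec.fm_prime - rec.ft / rec.fm
    yno = rec.ft / rec.fm
    flags = []
    if rec.fm_prime > fo_p:
        qp = (rec.fm_prime - rec.ft) / (rec.fm_prime - fo_p)
        ql = qp * fo_p / rec.ft
    else:
        qp = ql = None
        flags.append("qp_undefined")
    etr = 0.5 * 0.84 * rec.par * yii if rec.par is not None else None
    return FluorParams(
        fvfm=fv_fm,
        fvfo=fv_fo,
        yii=yii,
        npq=npq,
        qn=qn,
        qp=qp,
        ql=ql,
        ynpq=ynpq,
        yno=yno,
        etr=etr,
        fo_prime=float(fo_p),
        flags=tuple(flags),
    )


def treatment_comparison(values_a, values_b) -> dict:
    """Percent change and ratio of treatment a relative to reference b.

    Returns ``percent_change`` = 100*(mean_a - mean_b)/mean_b, ``ratio`` =
    100*mean_a/mean_b, and a Welch (unequal-variance) t-test p-value when both
    sides have >= 2 replicates.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    mean_a, mean_b = a.mean(), b.mean()
    if mean_b == 0:
        raise ValueError("reference mean must be nonzero")
    result = {
        "percent_change": 100.0 * (mean_a - mean_b) / mean_b,
        "ratio": 100.0 * mean_a / mean_b,
    }
    if a.size >= 2 and b.size >= 2:
        t, p = stats.ttest_ind(a, b, equal_var=False)
        result["t"] = float(t)
        result["p_value"] = float(p)
    return result
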