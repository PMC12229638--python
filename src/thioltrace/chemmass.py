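"""Elemental-formula and ion m/z arithmetic for the Br-OTPP derivatization assay.

The derivatization probe Br-OTPP ((3-(3-bromopyrrolidin-1-yl)propyl)-
triphenylphosphonium, cation composition C25H28BrNP, charge +1) alkylates free
sulfhydryl groups, expelling HBr, so the mass model of a labeled thiol is
strictly additive::

    derivative cation = probe cation + thiol - HBr        (charge stays +1)

All masses are monoisotopic, summed from a packaged NIST/CODATA table (8
decimals), and every ion m/z is electron-mass corrected.  Displayed m/z are
conventionally rounded to 4 decimals; full precision is kept internally.
"""

from __future__ import annotations

import csv
import re
import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, Iterator, Mapping

__all__ = [
    "ATOMIC_MASSES",
    "ELECTRON_MASS",
    "PROTON_MASS",
    "Formula",
    "FormulaError",
    "ProbeSpec",
    "AdductSpec",
    "MassError",
    "parse_formula",
    "monoisotopic_mass",
    "cation_mz",
    "derivative_formula",
    "derivative_mz",
    "adduct_mz",
    "ppm_error",
    "default_probe",
    "default_adducts",
]

#: Mass of the electron in Da, subtracted once per positive charge.
ELECTRON_MASS = 0.00054858


def _load_atomic_masses() -> Dict[str, float]:
    text = resources.files("thioltrace.data").joinpath("atomic_masses.csv").read_text()
    rows = csv.DictReader(text.splitlines())
    return {r["element"]: float(r["monoisotopic_mass"]) for r in rows}


#: element symbol -> monoisotopic mass of the most abundant isotope (Da)
ATOMIC_MASSES: Dict[str, float] = _load_atomic_masses()

#: m/z of a bare proton (H minus one electron)
PROTON_MASS = ATOMIC_MASSES["H"] - ELECTRON_MASS


class FormulaError(ValueError):
    """Raised for unparseable or chemically invalid formula strings."""


_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass(frozen=True)
class Formula(Mapping[str, int]):
    """An immutable element -> count map with additive composition algebra.

    Supports ``+`` and ``-`` (composition bookkeeping; subtraction raises if
    any count would go negative), hashing, and Hill-order canonicalisation
    (C, H, then remaining elements alphabetically).
    """

    counts: tuple = field(default=())  # tuple of (element, count), Hill order

    # -- construction -----------------------------------------------------
    @staticmethod
    def from_dict(d: Mapping[str, int]) -> "Formula":
        clean = {}
        for el, n in d.items():
            if el not in ATOMIC_MASSES:
                raise FormulaError(f"unknown element symbol: {el!r}")
            n = int(n)
            if n < 0:
                raise FormulaError(f"negative count for {el}: {n}")
            if n > 0:
                clean[el] = n
        order = sorted(clean, key=lambda e: (e != "C", e != "H", e))
        return Formula(tuple((e, clean[e]) for e in order))

    @staticmethod
    def parse(text: str) -> "Formula":
        """Parse plain Hill notation, e.g. ``"C6H12N2O4S"``."""
        if not isinstance(text, str) or not text.strip():
            raise FormulaError("empty formula string")
        text = text.strip()
        counts: Dict[str, int] = {}
        pos = 0
        while pos < len(text):
            m = _TOKEN.match(text, pos)
            if not m or m.start() != pos or not m.group(1):
                raise FormulaError(f"cannot parse formula {text!r} at {text[pos:]!r}")
            el, num = m.group(1), m.group(2)
            if el not in ATOMIC_MASSES:
                raise FormulaError(f"unknown element symbol {el!r} in {text!r}")
            n = int(num) if num else 1
            if n <= 0:
                raise FormulaError(f"zero count for {el!r} in {text!r}")
            counts[el] = counts.get(el, 0) + n
            pos = m.end()
        return Formula.from_dict(counts)

    # -- mapping protocol -------------------------------------------------
    def __getitem__(self, el: str) -> int:
        return dict(self.counts)[el]

    def __iter__(self) -> Iterator[str]:
        return iter(e for e, _ in self.counts)

    def __len__(self) -> int:
        return len(self.counts)

    def get(self, el: str, default: int = 0) -> int:
        return dict(self.counts).get(el, default)

    # -- algebra ----------------------------------------------------------
    def __add__(self, other: "Formula") -> "Formula":
        d = dict(self.counts)
        for el, n in other.counts:
            d[el] = d.get(el, 0) + n
        return Formula.from_dict(d)

    def __sub__(self, other: "Formula") -> "Formula":
        d = dict(self.counts)
        for el, n in other.counts:
            d[el] = d.get(el, 0) - n
            if d[el] < 0:
                raise FormulaError(
                    f"subtraction {self.hill()} - {other.hill()} drives {el} negative"
                )
        return Formula.from_dict(d)

    # -- rendering --------------------------------------------------------
    def hill(self) -> str:
        return "".join(f"{e}{n if n > 1 else ''}" for e, n in self.counts)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.hill()

    @property
    def mass(self) -> float:
        """Neutral monoisotopic mass in Da (0.0 for the empty formula)."""
        return sum(ATOMIC_MASSES[e] * n for e, n in self.counts)


def parse_formula(text: str) -> Formula:
    """Parse a Hill-style formula string into a :class:`Formula`."""
    return Formula.parse(text)


def monoisotopic_mass(f: Formula | str) -> float:
    """Neutral monoisotopic mass (Da) of ``f`` (formula or Hill string)."""
    if isinstance(f, str):
        f = Formula.parse(f)
    return f.mass


def cation_mz(f: Formula | str, charge: int = 1) -> float:
    """m/z of a cation of composition ``f`` carrying ``charge`` positive charges.

    The composition is the literal atom inventory of the ion; ``charge``
    electrons' worth of mass is subtracted before dividing.
    """
    if isinstance(f, str):
        f = Formula.parse(f)
    if int(charge) < 1:
        raise ValueError(f"charge must be a positive integer, got {charge}")
    charge = int(charge)
    return (f.mass - charge * ELECTRON_MASS) / charge


@dataclass(frozen=True)
class ProbeSpec:
    """A charged derivatization tag and its reaction bookkeeping.

    ``derivative = cation_formula + analyte - leaving_group`` (charge +1).
    The diagnostic fragment is the tag-side product ion shared by every
    derivative of this probe; its composition is configurable because only
    the nominal m/z is printed on most instruments' reports.
    """

    cation_formula: Formula = field(default_factory=lambda: Formula.parse("C25H28BrNP"))
    leaving_group: Formula = field(default_factory=lambda: Formula.parse("HBr"))
    diagnostic_fragment_formula: Formula | None = field(
        default_factory=lambda: Formula.parse("C25H29NPS")
    )
    diagnostic_fragment_mz: float | None = None

    @property
    def cation_mz(self) -> float:
        return cation_mz(self.cation_formula, 1)

    @property
    def reporter_mz(self) -> float:
        """m/z of the diagnostic fragment (explicit value wins over formula)."""
        if self.diagnostic_fragment_mz is not None:
            return self.diagnostic_fragment_mz
        if self.diagnostic_fragment_formula is not None:
            return cation_mz(self.diagnostic_fragment_formula, 1)
        raise ValueError("probe defines no diagnostic fragment")


def default_probe() -> ProbeSpec:
    """The Br-OTPP probe: C25H28BrNP(+), HBr loss, C25H29NPS(+) reporter."""
    return ProbeSpec()


def derivative_formula(thiol: Formula | str, probe: ProbeSpec | None = None) -> Formula:
    """Composition of the singly charged probe-thiol conjugate cation."""
    if isinstance(thiol, str):
        thiol = Formula.parse(thiol)
    probe = probe or default_probe()
    if thiol.get("S", 0) < 1:
        warnings.warn(
            f"analyte {thiol.hill()} contains no sulfur; "
            "derivative mass computed anyway",
            stacklevel=2,
        )
    return probe.cation_formula + thiol - probe.leaving_group


def derivative_mz(thiol: Formula | str, probe: ProbeSpec | None = None) -> float:
    """Theoretical m/z of the singly charged Br-OTPP derivative of ``thiol``."""
    return cation_mz(derivative_formula(thiol, probe), 1)


@dataclass(frozen=True)
class AdductSpec:
    """A named ionisation adduct: m/z = (M + delta - z*e) / z."""

    name: str
    delta_formula: Formula
    charge: int = 1

    def __post_init__(self):
        if self.charge < 1:
            raise ValueError(f"adduct charge must be >= 1, got {self.charge}")

    def mz(self, neutral: Formula | str) -> float:
        if isinstance(neutral, str):
            neutral = Formula.parse(neutral)
        return (
            neutral.mass + self.delta_formula.mass - self.charge * ELECTRON_MASS
        ) / self.charge


def _load_adducts() -> Dict[str, AdductSpec]:
    text = resources.files("thioltrace.data").joinpath("adducts.csv").read_text()
    out = {}
    for r in csv.DictReader(text.splitlines()):
        out[r["name"]] = AdductSpec(
            name=r["name"],
            delta_formula=Formula.parse(r["delta_formula"]),
            charge=int(r["charge"]),
        )
    return out


_ADDUCTS = _load_adducts()


def default_adducts() -> Dict[str, AdductSpec]:
    """The packaged adduct registry (M+H, M+Na)."""
    return dict(_ADDUCTS)


def adduct_mz(neutral: Formula | str, adduct: str | AdductSpec) -> float:
    """m/z of ``neutral`` ionised as ``adduct`` (name or explicit spec)."""
    if isinstance(adduct, str):
        key = adduct.replace(" ", "")
        try:
            adduct = _ADDUCTS[key]
        except KeyError:
            raise KeyError(
                f"unknown adduct {adduct!r}; registered: {sorted(_ADDUCTS)}"
            ) from None
    return adduct.mz(neutral)


@dataclass(frozen=True)
class MassError:
    """Signed relative mass deviation: ppm = 1e6 * (obs - theo) / theo."""

    observed_mz: float
    theoretical_mz: float

    @property
    def ppm(self) -> float:
        return 1e6 * (self.observed_mz - self.theoretical_mz) / self.theoretical_mz


def ppm_error(observed: float, theoretical: float) -> MassError:
    """Signed ppm error of ``observed`` against ``theoretical`` (> 0)."""
    if theoretical <= 0:
        raise ValueError(f"theoretical m/z must be positive, got {theoretical}")
    return MassError(observed_mz=observed, theoretical_mz=theoretical)
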