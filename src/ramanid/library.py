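"""Packaged Raman fingerprint library and concentration utilities.

The library holds one :class:`FingerprintRecord` per reference pesticide:
its identity (name, CAS, agrochemical and chemical class), molecular
formula, and its measured major/minor Raman peak positions with inert
vibrational-assignment annotations.  Molar masses are computed at load
time from the molecular formula against a packaged IUPAC atomic-weight
table rather than stored, so concentration conversions are independent of
transcription errors.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from typing import Sequence

from .errors import ConfigError, ParseError, ValidationError
from .features import Peak, peak_concordance

__all__ = [
    "FingerprintRecord",
    "load_library",
    "molar_mass_from_formula",
    "ppm_from_micromolar",
    "match_to_library",
]

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass(frozen=True)
class FingerprintRecord:
    """One pesticide's fingerprint: identity, formula, and Raman peak lists."""

    name: str
    cas: str
    agro_class: str
    chem_class: str
    molecular_formula: str
    major_peaks: tuple[float, ...]
    minor_peaks: tuple[float, ...]
    assignments: str = ""
    molar_mass: float = field(default=0.0)

    def all_peaks(self) -> list[float]:
        return sorted(set(self.major_peaks) | set(self.minor_peaks))


@lru_cache(maxsize=1)
def _atomic_weights() -> dict[str, float]:
    text = resources.files("ramanid.data").joinpath("atomic_weights.json").read_text()
    table = json.loads(text)
    return {k: float(v) for k, v in table.items() if not k.startswith("_")}


def molar_mass_from_formula(formula: str) -> float:
    """Molar mass (g/mol) of a Hill-notation formula like ``C15H21NO4``.

    Parentheses and isotopes are not supported; an unknown element symbol
    raises :class:`ParseError`.
    """
    if not formula or not formula.strip():
        raise ParseError("empty molecular formula")
    formula = formula.strip()
    weights = _atomic_weights()
    mass = 0.0
    pos = 0
    for m in _FORMULA_TOKEN.finditer(formula):
        if m.start() != pos:
            raise ParseError(f"cannot parse formula {formula!r} at position {pos}")
        if not m.group(0):
            break
        sym, count = m.group(1), m.group(2)
        if sym not in weights:
            raise ParseError(f"unknown element symbol {sym!r} in formula {formula!r}")
        mass += weights[sym] * (int(count) if count else 1)
        pos = m.end()
    if pos != len(formula):
        raise ParseError(f"cannot parse formula {formula!r} at position {pos}")
    return mass


def ppm_from_micromolar(conc_um: float, molar_mass: float) -> float:
    """Convert a micromolar concentration to ppm (mg/L, dilute aqueous assumption).

    conc [umol/L] * M [g/mol] = conc*M [ug/L]; divided by 1000 -> mg/L.
    """
    if conc_um < 0:
        raise ValidationError(f"concentration must be >= 0, got {conc_um}")
    if molar_mass <= 0:
        raise ValidationError(f"molar mass must be > 0, got {molar_mass}")
    return conc_um * molar_mass / 1000.0


def _validate_record(r: FingerprintRecord) -> None:
    for peaks, kind in ((r.major_peaks, "major"), (r.minor_peaks, "minor")):
        if list(peaks) != sorted(peaks):
            raise ValidationError(f"{r.name}: {kind} peaks not sorted ascending")
        if len(set(peaks)) != len(peaks):
            raise ValidationError(f"{r.name}: duplicate {kind} peak")
        for p in peaks:
            if not 400 <= p <= 1800:
                raise ValidationError(f"{r.name}: {kind} peak {p} outside [400, 1800]")
    if r.molar_mass <= 0:
        raise ValidationError(f"{r.name}: non-positive molar mass")
    if not r.major_peaks:
        raise ValidationError(f"{r.name}: no major peaks")


@lru_cache(maxsize=1)
def load_library() -> tuple[FingerprintRecord, ...]:
    """The packaged 14-record fingerprint library, validated at load."""
    text = resources.files("ramanid.data").joinpath("fingerprints.json").read_text()
    payload = json.loads(text)
    records = []
    for d in payload["records"]:
        rec = FingerprintRecord(
            name=d["name"],
            cas=d["cas"],
            agro_class=d["agro_class"],
            chem_class=d["chem_class"],
            molecular_formula=d["molecular_formula"],
            major_peaks=tuple(float(p) for p in d["major_peaks"]),
            minor_peaks=tuple(float(p) for p in d["minor_peaks"]),
            assignments=d.get("assignments", ""),
            molar_mass=molar_mass_from_formula(d["molecular_formula"]),
        )
        _validate_record(rec)
        records.append(rec)
    if len(records) != 14:
        raise ValidationError(f"fingerprint library must hold 14 records, found {len(records)}")
    if len({r.name for r in records}) != len(records):
        raise ValidationError("duplicate record names in fingerprint library")
    return tuple(records)


def get_record(name: str) -> FingerprintRecord:
    """Case-insensitive lookup of one library record by pesticide name."""
    for r in load_library():
        if r.name.lower() == name.lower():
            return r
    raise KeyError(f"no fingerprint record named {name!r}")


def match_to_library(
    peaks: Sequence[Peak | float],
    library: Sequence[FingerprintRecord] | None = None,
    tol: float = 5.0,
) -> list[tuple[FingerprintRecord, float]]:
    """Rank library records against a query peak list.

    Score per record = (2 * concordance of its major peaks with the query
    + 1 * concordance of its minor peaks) / 3, concordance being the
    greedy one-to-one matched fraction within ``tol`` cm^-1.  Ties are
    broken by record name.
    """
    if tol <= 0:
        raise ConfigError("tol must be > 0")
    if library is None:
        library = load_library()
    if not library:
        raise ValidationError("empty fingerprint library")
    scored = []
    for rec in library:
        if peaks:
            cm = peak_concordance(rec.major_peaks, peaks, tol=tol)
            cn = peak_concordance(rec.minor_peaks, peaks, tol=tol) if rec.minor_peaks else 0.0
            weight_minor = 1.0 if rec.minor_peaks else 0.0
            score = (2.0 * cm + weight_minor * cn) / (2.0 + weight_minor)
        else:
            score = 0.0
        scored.append((rec, score))
    scored.sort(key=lambda t: (-t[1], t[0].name))
    return scored
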