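"""Reading and writing spectra and label manifests.

File conventions
----------------
* One spectrum per file: two numeric columns ``wavenumber,intensity``
  (CSV or TSV), optional single header line.  Rows may arrive unsorted;
  they are sorted on read.  Duplicate wavenumbers are rejected rather than
  averaged so instrument-export bugs surface early.
* A manifest CSV with columns ``path,label,replicate,excitation_nm``
  describes a whole dataset.  Without a manifest, metadata is recovered
  from the filename convention ``<label>__<replicate>.csv``.
"""

from __future__ import annotations

import json
import os
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import ParseError, ValidationError
from .spectrum import RamanSpectrum, SpectrumSet

__all__ = [
    "read_spectrum",
    "write_spectrum",
    "read_manifest",
    "write_manifest",
    "load_spectrum_set",
    "save_spectrum_set",
    "spectrum_set_to_json",
    "spectrum_set_from_json",
]

_DELIMS = {"csv": ",", "tsv": "\t"}


def _sniff_delimiter(first_line: str) -> str:
    if "\t" in first_line:
        return "\t"
    if "," in first_line:
        return ","
    return None  # whitespace-separated


def read_spectrum(
    path: str | os.PathLike,
    dialect: str | None = None,
    label: str | None = None,
    excitation_nm: float | None = None,
    replicate_id: str | None = None,
) -> RamanSpectrum:
    """Read a two-column wavenumber/intensity file into a :class:`RamanSpectrum`.

    ``dialect`` is ``"csv"``, ``"tsv"`` or ``None`` (auto-detect delimiter).
    An optional one-line non-numeric header is skipped.  Metadata defaults
    come from the ``<label>__<replicate>`` filename convention.
    """
    path = Path(path)
    if not path.is_file():
        raise ParseError(f"no such spectrum file: {path}")
    if dialect is not None and dialect not in _DELIMS:
        raise ParseError(f"unknown dialect {dialect!r}; expected 'csv' or 'tsv'")

    lines = path.read_text().splitlines()
    rows: list[tuple[float, float]] = []
    delim = _DELIMS[dialect] if dialect is not None else None
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if delim is None and not rows:
            delim = _sniff_delimiter(line)
        parts = line.split(delim) if delim else line.split()
        parts = [p.strip() for p in parts if p.strip() != ""]
        if len(parts) < 2:
            raise ParseError(f"{path}: line {lineno}: expected two columns, got {len(parts)}")
        try:
            wn, iy = float(parts[0]), float(parts[1])
        except ValueError:
            if lineno == 1 and not rows:
                continue  # header line
            raise ParseError(
                f"{path}: line {lineno}: non-numeric value in {parts[:2]!r}"
            ) from None
        rows.append((wn, iy))

    if len(rows) < 8:
        raise ValidationError(f"{path}: only {len(rows)} data rows; at least 8 required")
    arr = np.asarray(rows, dtype=float)
    order = np.argsort(arr[:, 0], kind="stable")
    arr = arr[order]
    if np.any(np.diff(arr[:, 0]) == 0):
        dup = arr[:-1, 0][np.diff(arr[:, 0]) == 0][0]
        raise ValidationError(f"{path}: duplicate wavenumber {dup}")

    if label is None or replicate_id is None:
        stem_label, stem_rep = _parse_stem(path.stem)
        label = label if label is not None else stem_label
        replicate_id = replicate_id if replicate_id is not None else stem_rep
    return RamanSpectrum(
        wavenumbers=arr[:, 0],
        intensities=arr[:, 1],
        label=label,
        excitation_nm=excitation_nm,
        replicate_id=replicate_id,
        source_path=str(path),
    )


def _parse_stem(stem: str) -> tuple[str, str]:
    if "__" in stem:
        label, _, rep = stem.partition("__")
        return label or "unknown", rep
    return "unknown", ""


def write_spectrum(s: RamanSpectrum, path: str | os.PathLike, dialect: str = "csv") -> None:
    """Write a spectrum with full float precision so read/write round-trips exactly."""
    delim = _DELIMS[dialect]
    with open(path, "w") as fh:
        fh.write(f"wavenumber{delim}intensity\n")
        for wn, iy in zip(s.wavenumbers, s.intensities):
            fh.write(f"{float(wn)!r}{delim}{float(iy)!r}\n")


def read_manifest(path: str | os.PathLike) -> pd.DataFrame:
    """Read a ``path,label,replicate,excitation_nm`` manifest CSV."""
    path = Path(path)
    if not path.is_file():
        raise ParseError(f"no such manifest: {path}")
    df = pd.read_csv(path, dtype={"path": str, "label": str, "replicate": str})
    missing = {"path", "label"} - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: manifest missing columns {sorted(missing)}")
    if "replicate" not in df.columns:
        df["replicate"] = [str(i) for i in range(len(df))]
    if "excitation_nm" not in df.columns:
        df["excitation_nm"] = np.nan
    return df


def write_manifest(rows: Iterable[dict], path: str | os.PathLike) -> None:
    pd.DataFrame(list(rows)).to_csv(path, index=False)


def load_spectrum_set(manifest_path: str | os.PathLike, dialect: str | None = None) -> SpectrumSet:
    """Load every spectrum listed in a manifest, relative to the manifest's directory."""
    manifest_path = Path(manifest_path)
    df = read_manifest(manifest_path)
    base = manifest_path.parent
    spectra = []
    for row in df.itertuples(index=False):
        p = Path(row.path)
        if not p.is_absolute():
            p = base / p
        exc = float(row.excitation_nm) if np.isfinite(row.excitation_nm) else None
        spectra.append(
            read_spectrum(p, dialect=dialect, label=row.label,
                          replicate_id=str(row.replicate), excitation_nm=exc)
        )
    return SpectrumSet.from_spectra(spectra)


def save_spectrum_set(
    sset: SpectrumSet, out_dir: str | os.PathLike, dialect: str = "csv"
) -> Path:
    """Write one file per spectrum plus a manifest; returns the manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, s in enumerate(sset):
        rep = s.replicate_id or str(i)
        fname = f"{s.label}__{rep}.{dialect}"
        write_spectrum(s, out_dir / fname, dialect=dialect)
        rows.append(
            {
                "path": fname,
                "label": s.label,
                "replicate": rep,
                "excitation_nm": s.excitation_nm if s.excitation_nm is not None else "",
            }
        )
    manifest = out_dir / "manifest.csv"
    write_manifest(rows, manifest)
    return manifest


def spectrum_set_to_json(sset: SpectrumSet) -> str:
    """Serialize a SpectrumSet to a JSON string (used for small test fixtures)."""
    payload = {
        "class_names": sset.class_names,
        "spectra": [
            {
                "wavenumbers": s.wavenumbers.tolist(),
                "intensities": s.intensities.tolist(),
                "label": s.label,
                "excitation_nm": s.excitation_nm,
                "replicate_id": s.replicate_id,
            }
            for s in sset
        ],
    }
    return json.dumps(payload)


def spectrum_set_from_json(text: str) -> SpectrumSet:
    payload = json.loads(text)
    spectra = [
        RamanSpectrum(
            wavenumbers=np.asarray(d["wavenumbers"], dtype=float),
            intensities=np.asarray(d["intensities"], dtype=float),
            label=d.get("label", "unknown"),
            excitation_nm=d.get("excitation_nm"),
            replicate_id=d.get("replicate_id", ""),
        )
        for d in payload["spectra"]
    ]
    return SpectrumSet(spectra=spectra, class_names=list(payload["class_names"]))
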