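"""Readers and writers for spectra and feature matrices.

Spectra are read either from two-column delimited text (ppm, intensity;
header optional) or from single-spectrum 1-D JCAMP-DX files (AFFN-encoded
``(X++(Y..Y))`` and ``(XY..XY)`` tables). Feature matrices round-trip as a
delimited table (first column sample_id, remaining columns named by bin
center) plus a JSON sidecar with the stage flags and bin grid.
"""

from __future__ import annotations

import json
import re
from pathlib import Path

import numpy as np
import pandas as pd

from .spectra import FeatureMatrix, RawSpectrum

_NUM = re.compile(r"[+-]?(?:\d+\.?\d*|\.\d+)(?:[eE][+-]?\d+)?")


def read_two_column(path: str | Path, sample_id: str | None = None) -> RawSpectrum:
    """Read a (ppm, intensity) delimited file; delimiter is sniffed."""
    path = Path(path)
    df = pd.read_csv(path, sep=None, engine="python", comment="#", header=None)
    # drop a header row if the first row is non-numeric
    try:
        float(df.iloc[0, 0])
    except (TypeError, ValueError):
        df = df.iloc[1:]
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (ppm, intensity)")
    ppm = df.iloc[:, 0].astype(float).to_numpy()
    intensity = df.iloc[:, 1].astype(float).to_numpy()
    return RawSpectrum(ppm, intensity, sample_id or path.stem)


def _jcamp_records(text: str) -> dict[str, str]:
    """Split a JCAMP-DX file into labelled data records (last wins)."""
    records: dict[str, str] = {}
    label = None
    body: list[str] = []
    for line in text.splitlines():
        line = line.split("$$")[0].rstrip()
        if line.startswith("##"):
            if label is not None:
                records[label] = "\n".join(body)
            label, _, rest = line[2:].partition("=")
            label = label.strip().upper().replace(" ", "")
            body = [rest.strip()]
        elif label is not None:
            body.append(line)
    if label is not None:
        records[label] = "\n".join(body)
    return records


def read_jcamp(path: str | Path, sample_id: str | None = None) -> RawSpectrum:
    """Read a 1-D spectrum from a JCAMP-DX file (AFFN tables only)."""
    path = Path(path)
    rec = _jcamp_records(path.read_text())
    xfac = float(rec.get("XFACTOR", "1"))
    yfac = float(rec.get("YFACTOR", "1"))
    if "XYDATA" in rec:
        lines = rec["XYDATA"].splitlines()
        form = lines[0].upper().replace(" ", "")
        if "X++" not in form:
            raise ValueError(f"{path}: unsupported XYDATA form {lines[0]!r}")
        xs: list[float] = []
        ys: list[float] = []
        rows = []
        for line in lines[1:]:
            vals = [float(v) for v in _NUM.findall(line)]
            if len(vals) >= 2:
                rows.append(vals)
        npoints = int(float(rec.get("NPOINTS", "0"))) or sum(len(r) - 1 for r in rows)
        firstx = float(rec["FIRSTX"])
        lastx = float(rec["LASTX"])
        step = (lastx - firstx) / (npoints - 1)
        for row in rows:
            x0 = row[0] * xfac
            for j, y in enumerate(row[1:]):
                xs.append(x0 + j * step)
                ys.append(y * yfac)
        ppm = np.array(xs)
        intensity = np.array(ys)
    elif "XYPOINTS" in rec or "PEAKTABLE" in rec:
        key = "XYPOINTS" if "XYPOINTS" in rec else "PEAKTABLE"
        lines = rec[key].splitlines()[1:]
        pairs = [float(v) for line in lines for v in _NUM.findall(line)]
        if len(pairs) % 2:
            raise ValueError(f"{path}: odd number of values in {key}")
        arr = np.array(pairs).reshape(-1, 2)
        ppm = arr[:, 0] * xfac
        intensity = arr[:, 1] * yfac
    else:
        raise ValueError(f"{path}: no XYDATA/XYPOINTS record found")
    return RawSpectrum(ppm, intensity, sample_id or path.stem).ascending


def read_spectrum(path: str | Path) -> RawSpectrum:
    """Dispatch on extension: .jdx/.dx -> JCAMP-DX, else two-column text."""
    path = Path(path)
    if path.suffix.lower() in {".jdx", ".dx", ".jcamp"}:
        return read_jcamp(path)
    return read_two_column(path)


def read_spectra_dir(directory: str | Path) -> list[RawSpectrum]:
    """Read every spectrum file in a directory, sorted by filename."""
    directory = Path(directory)
    exts = {".csv", ".tsv", ".txt", ".jdx", ".dx", ".jcamp"}
    paths = sorted(p for p in directory.iterdir() if p.suffix.lower() in exts)
    if not paths:
        raise FileNotFoundError(f"no spectrum files found in {directory}")
    return [read_spectrum(p) for p in paths]


def write_feature_matrix(m: FeatureMatrix, path: str | Path,
                         sidecar: dict | None = None) -> Path:
    """Write a feature matrix as CSV + JSON sidecar (``<path>.json``)."""
    path = Path(path)
    cols = [f"{c:.4f}" for c in m.bin_centers]
    df = pd.DataFrame(m.values, columns=cols)
    df.insert(0, "sample_id", m.sample_ids)
    df.to_csv(path, index=False)
    meta = {
        "bin_width": m.bin_width,
        "bin_centers_first": float(m.bin_centers[0]),
        "bin_centers_last": float(m.bin_centers[-1]),
        "n_bins": int(m.n_bins),
        "stage_flags": sorted(m.stage_flags),
    }
    if m.column_means is not None:
        meta["column_means"] = [float(v) for v in m.column_means]
    if sidecar:
        meta.update(sidecar)
    Path(str(path) + ".json").write_text(json.dumps(meta, indent=2, sort_keys=True))
    return path


def read_feature_matrix(path: str | Path) -> FeatureMatrix:
    """Read a feature matrix written by :func:`write_feature_matrix`."""
    path = Path(path)
    df = pd.read_csv(path)
    sample_ids = df["sample_id"].astype(str).tolist()
    centers = np.array([float(c) for c in df.columns[1:]])
    values = df.iloc[:, 1:].to_numpy(dtype=float)
    meta_path = Path(str(path) + ".json")
    flags: frozenset[str] = frozenset()
    width = float(np.median(np.diff(centers))) if centers.size > 1 else 0.005
    means = None
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
        flags = frozenset(meta.get("stage_flags", []))
        width = float(meta.get("bin_width", width))
        if "column_means" in meta:
            means = np.asarray(meta["column_means"], dtype=float)
    return FeatureMatrix(values, centers, width, sample_ids, flags, means)
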