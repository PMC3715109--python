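"""Chemical-shift annotation of discriminating bins.

Maps bin centers to candidate metabolites by tolerance-based lookup in a
:class:`~nmrfinger.simulate.MetaboliteLibrary` (standing in for the HMDB /
Chenomx lookups done in practice). A bin may match several metabolites —
shift overlap is real (e.g. 7.15 ppm is both a histamine and a xanthurenic
acid resonance) and is reported, not resolved.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import MetaboliteLibrary

DEFAULT_TOLERANCE = 0.01  # ppm; two default bin widths


@dataclass
class Annotation:
    """All library matches within tolerance for one bin."""

    bin_center: float
    matches: list[tuple[str, float, float]]  # (metabolite, shift, distance)
    direction: str | None = None  # up/down in the positive class
    rank: int | None = None

    def metabolite_names(self) -> list[str]:
        """Matched metabolites, deduplicated, nearest first."""
        return list(dict.fromkeys(m for m, _, _ in self.matches))


def match_bins(
    bins,
    library: MetaboliteLibrary,
    tolerance: float = DEFAULT_TOLERANCE,
    directions=None,
) -> list[Annotation]:
    """Annotate each bin center with library shifts within ``tolerance``.

    ``bins`` is an iterable of ppm centers or a DataFrame with a
    ``bin_center`` column (and optionally ``direction``). Matches are sorted
    by distance (ties alphabetical); bins without a match keep an empty
    list. Deterministic and independent of input order.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    if isinstance(bins, pd.DataFrame):
        centers = bins["bin_center"].to_numpy(dtype=float)
        if directions is None and "direction" in bins.columns:
            directions = bins["direction"].tolist()
    else:
        centers = np.asarray(list(bins), dtype=float)
    out: list[Annotation] = []
    for rank, c in enumerate(centers):
        matches = []
        for name, shifts in library.entries.items():
            for s in shifts:
                d = abs(c - s)
                if d <= tolerance:
                    matches.append((name, s, d))
        matches.sort(key=lambda m: (m[2], m[0], m[1]))
        direction = None
        if directions is not None:
            direction = directions[rank]
        out.append(Annotation(float(c), matches, direction, rank + 1))
    return out


def annotations_to_frame(annotations: list[Annotation]) -> pd.DataFrame:
    """Long-format table: one row per (bin, matched metabolite)."""
    rows = []
    for a in annotations:
        if not a.matches:
            rows.append({"rank": a.rank, "bin_center": a.bin_center,
                         "metabolite": None, "library_shift": np.nan,
                         "distance": np.nan, "direction": a.direction})
        for name, shift, dist in a.matches:
            rows.append({"rank": a.rank, "bin_center": a.bin_center,
                         "metabolite": name, "library_shift": shift,
                         "distance": dist, "direction": a.direction})
    return pd.DataFrame(rows)


def consensus_metabolites(
    method_annotations: dict[str, list[Annotation]],
) -> pd.DataFrame:
    """Count, per metabolite, the methods whose annotated bins include it.

    Sorted by method count (descending), then best rank across methods.
    Direction is reported from the PLS-DA method's signs when available
    (the other rankings are unsigned).
    """
    if len(method_annotations) < 2:
        raise ValueError("need annotations from at least 2 methods")
    seen: dict[str, dict] = {}
    for method, annotations in method_annotations.items():
        for a in annotations:
            for name, _, _ in a.matches:
                rec = seen.setdefault(
                    name, {"methods": set(), "best_rank": np.inf, "direction": None}
                )
                rec["methods"].add(method)
                if a.rank is not None:
                    rec["best_rank"] = min(rec["best_rank"], a.rank)
                if method == "plsda" and rec["direction"] is None:
                    rec["direction"] = a.direction
    rows = [
        {
            "metabolite": name,
            "n_methods": len(rec["methods"]),
            "methods": ",".join(sorted(rec["methods"])),
            "best_rank": (int(rec["best_rank"])
                          if np.isfinite(rec["best_rank"]) else None),
            "direction": rec["direction"],
        }
        for name, rec in seen.items()
    ]
    rows.sort(key=lambda r: (-r["n_methods"],
                             r["best_rank"] if r["best_rank"] else np.inf,
                             r["metabolite"]))
    return pd.DataFrame(rows)


def read_library(path: str | Path) -> MetaboliteLibrary:
    """Read a (metabolite, shift_ppm) delimited file into a library."""
    df = pd.read_csv(path, sep=None, engine="python")
    df.columns = [c.strip().lower() for c in df.columns]
    name_col, shift_col = df.columns[:2]
    entries: dict[str, list[float]] = {}
    for _, row in df.iterrows():
        entries.setdefault(str(row[name_col]), []).append(float(row[shift_col]))
    return MetaboliteLibrary({k: tuple(v) for k, v in entries.items()})


def write_library(library: MetaboliteLibrary, path: str | Path) -> Path:
    path = Path(path)
    rows = [(name, s) for name, shifts in library.entries.items() for s in shifts]
    pd.DataFrame(rows, columns=["metabolite", "shift_ppm"]).to_csv(path, index=False)
    return path
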