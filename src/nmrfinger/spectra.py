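"""Core in-memory containers shared across the pipeline.

A :class:`RawSpectrum` is one sample's continuous 1-D spectrum on a ppm
axis; a :class:`FeatureMatrix` is the samples x bins table produced by
binning, carrying its bin grid and a record of which preprocessing stages
have been applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

#: Canonical order of preprocessing stages. Out-of-order application is
#: rejected by the preprocess module.
STAGES = (
    "calibrated",
    "truncated",
    "binned",
    "baseline_corrected",
    "normalized",
    "glog",
    "centered",
)


@dataclass(frozen=True)
class RawSpectrum:
    """One sample's 1-D spectrum: ppm axis, intensities, identity."""

    ppm: np.ndarray
    intensity: np.ndarray
    sample_id: str = ""

    def __post_init__(self) -> None:
        ppm = np.asarray(self.ppm, dtype=float)
        intensity = np.asarray(self.intensity, dtype=float)
        object.__setattr__(self, "ppm", ppm)
        object.__setattr__(self, "intensity", intensity)
        if ppm.ndim != 1 or intensity.ndim != 1:
            raise ValueError("ppm and intensity must be 1-D arrays")
        if ppm.size != intensity.size:
            raise ValueError(
                f"ppm ({ppm.size}) and intensity ({intensity.size}) lengths differ"
            )
        if ppm.size < 2:
            raise ValueError("spectrum needs at least 2 points")
        d = np.diff(ppm)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("ppm axis must be strictly monotone")

    @property
    def ascending(self) -> "RawSpectrum":
        """Return the spectrum with the ppm axis sorted ascending."""
        if self.ppm[0] < self.ppm[-1]:
            return self
        return RawSpectrum(self.ppm[::-1].copy(), self.intensity[::-1].copy(),
                           self.sample_id)

    def shifted(self, delta: float) -> "RawSpectrum":
        """Return a copy with ``delta`` added to the ppm axis."""
        return RawSpectrum(self.ppm + delta, self.intensity, self.sample_id)


@dataclass
class FeatureMatrix:
    """Samples x bins intensity matrix with provenance flags.

    ``stage_flags`` records which preprocessing stages have been applied;
    ``column_means`` is populated by centering and is what held-out samples
    are projected with inside cross-validation.
    """

    values: np.ndarray
    bin_centers: np.ndarray
    bin_width: float
    sample_ids: list[str]
    stage_flags: frozenset[str] = field(default_factory=frozenset)
    column_means: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.bin_centers = np.asarray(self.bin_centers, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (samples x bins)")
        if self.values.shape[1] != self.bin_centers.size:
            raise ValueError("bin_centers length must match number of columns")
        if len(self.sample_ids) != self.values.shape[0]:
            raise ValueError("sample_ids length must match number of rows")
        d = np.diff(self.bin_centers)
        if self.bin_centers.size > 1:
            if np.any(d <= 0):
                raise ValueError("bin_centers must be strictly increasing")
            if not np.allclose(d, self.bin_width, atol=1e-9):
                raise ValueError("bin_centers must be equally spaced by bin_width")
        self.stage_flags = frozenset(self.stage_flags)
        unknown = self.stage_flags - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stage flags: {sorted(unknown)}")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_bins(self) -> int:
        return self.values.shape[1]

    def has_stage(self, stage: str) -> bool:
        return stage in self.stage_flags

    def with_values(self, values: np.ndarray, *, add_stage: str | None = None,
                    column_means: np.ndarray | None = None) -> "FeatureMatrix":
        flags = set(self.stage_flags)
        if add_stage is not None:
            flags.add(add_stage)
        return replace(
            self,
            values=np.asarray(values, dtype=float),
            stage_flags=frozenset(flags),
            column_means=self.column_means if column_means is None else column_means,
        )
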