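"""Synthetic urine NMR cohort generation.

Real urine spectra from the clinical cohorts this package targets are not
publicly deposited, so every downstream stage is exercised on synthetic
cohorts with known ground truth: mixtures of Lorentzian resonances at the
library chemical shifts, with group-dependent log-concentration shifts, a
per-sample multiplicative dilution factor (the variability that total-area
normalization removes), a constant baseline offset, and additive Gaussian
noise.

The metabolite library covers the discriminating urine metabolites of
anti-TNF response fingerprinting (histamine, glutamine, xanthurenic acid,
ethanolamine, and their companions) plus the metabolites reported to change
under therapy (hippuric acid, lactic acid, choline, urea, creatine,
methylamine), and always includes the TMSP reference resonance at 0.0 ppm
so chemical-shift calibration is exercised.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .spectra import RawSpectrum

#: Name of the chemical-shift reference compound (0.0 ppm).
REFERENCE = "TMSP"

# Chemical shifts (ppm) of the discriminating urine metabolites, pooled
# across the three ranking methods' reported peak lists.
_CORE_SHIFTS: dict[str, tuple[float, ...]] = {
    "histamine": (3.28, 7.12, 7.13, 7.15, 7.24, 8.00, 8.01),
    "glutamine": (2.12, 2.13, 2.16, 2.34),
    "xanthurenic acid": (6.96, 7.13, 7.15, 7.37),
    "ethanolamine": (3.16, 3.17, 3.74, 3.80),
    "citrate": (2.53, 2.56, 2.67),
    "creatinine": (3.04, 3.05, 4.05, 4.06),
    "phosphocreatine": (3.04, 3.05, 3.94),
    "thymine": (1.86, 7.35, 7.37),
    "p-hydroxyphenylpyruvic acid": (4.06, 6.82, 6.8225, 7.12, 7.14),
    "phenylacetic acid": (3.63, 7.29, 7.30, 7.32, 7.39, 7.44),
    "xanthine": (7.82, 7.90),
    "trimethylamine": (2.87,),
    "dimethylamine": (2.70,),
    "thiamine": (7.41,),
    "tartaric acid": (4.38,),
    "3-phosphoglyceric acid": (4.14,),
}

# Metabolites reported to change over 12 weeks of therapy or to separate
# infliximab from etanercept; their peak lists are not printed alongside, so
# standard urine-NMR shifts (HMDB-consistent) are used.
_TREATMENT_SHIFTS: dict[str, tuple[float, ...]] = {
    "hippuric acid": (3.97, 7.55, 7.64, 7.84),
    "lactic acid": (1.33, 4.11),
    "choline": (3.20,),
    "urea": (5.78,),
    "creatine": (3.03, 3.93),
    "methylamine": (2.61,),
}


@dataclass(frozen=True)
class MetaboliteLibrary:
    """Mapping of metabolite name -> chemical shifts (ppm)."""

    entries: dict[str, tuple[float, ...]]

    def __post_init__(self) -> None:
        cleaned: dict[str, tuple[float, ...]] = {}
        for name, shifts in self.entries.items():
            shifts = tuple(float(s) for s in shifts)
            if not shifts:
                raise ValueError(f"metabolite {name!r} has no shifts")
            for s in shifts:
                if s != 0.0 and not (0.8 <= s <= 10.0):
                    raise ValueError(
                        f"shift {s} of {name!r} outside [0.8, 10.0] "
                        "(only the 0.0-ppm reference is allowed outside)"
                    )
            if name in cleaned:
                raise ValueError(f"duplicate metabolite {name!r}")
            cleaned[name] = shifts
        object.__setattr__(self, "entries", cleaned)

    def __contains__(self, name: str) -> bool:
        return name in self.entries

    def __iter__(self):
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    def shifts(self, name: str) -> tuple[float, ...]:
        try:
            return self.entries[name]
        except KeyError:
            raise KeyError(f"metabolite {name!r} not in library") from None

    @property
    def names(self) -> list[str]:
        return list(self.entries)


def default_library() -> MetaboliteLibrary:
    """The packaged urine metabolite library, including the TMSP reference."""
    entries = dict(_CORE_SHIFTS)
    entries.update(_TREATMENT_SHIFTS)
    entries[REFERENCE] = (0.0,)
    return MetaboliteLibrary(entries)


# Typical relative urinary abundances (arbitrary concentration units,
# roughly creatinine-referenced). Total spectral area is dominated by the
# abundant metabolites (urea, creatinine, citrate, hippurate), so a fold
# change in a trace metabolite barely moves the normalization constant —
# the behavior real total-area normalization shows.
DEFAULT_ABUNDANCES: dict[str, float] = {
    "urea": 15.0,
    "creatinine": 10.0,
    "citrate": 4.0,
    "hippuric acid": 4.0,
    "lactic acid": 1.5,
    "creatine": 1.0,
    "glutamine": 0.6,
    "phenylacetic acid": 0.5,
    "dimethylamine": 0.5,
    "choline": 0.5,
    "ethanolamine": 0.4,
    "histamine": 0.3,
    "trimethylamine": 0.3,
    "methylamine": 0.3,
    "p-hydroxyphenylpyruvic acid": 0.3,
    "phosphocreatine": 0.3,
    "xanthine": 0.3,
    "tartaric acid": 0.3,
    "xanthurenic acid": 0.2,
    "thymine": 0.2,
    "3-phosphoglyceric acid": 0.2,
    "thiamine": 0.1,
}


@dataclass(frozen=True)
class CohortConfig:
    """Generation parameters for a two-group synthetic urine cohort.

    ``effect_map`` gives signed log-fold concentration shifts applied to
    group 1 relative to group 0. ``dilution_sd`` is the standard deviation
    of the per-sample log dilution factor; ``noise_sd`` the additive
    Gaussian noise level in intensity units; ``linewidth`` the Lorentzian
    half-width at half-maximum in ppm (0.005 ppm = 2.5 Hz at 500 MHz).
    ``outcome_means`` are the continuous-outcome group means (emulating the
    change in DAS28 for non-responders vs responders), ``outcome_sd`` its
    noise.
    """

    n_per_group: int = 8
    effect_map: dict[str, float] = field(default_factory=dict)
    dilution_sd: float = 0.3
    noise_sd: float = 0.01
    baseline_offset_range: float = 0.05
    linewidth: float = 0.002
    points_per_ppm: int = 1000
    seed: int = 0
    group_sizes: tuple[int, int] | None = None
    base_concentrations: dict[str, float] | None = None
    log_conc_sd: float = 0.25
    outcome_means: tuple[float, float] = (-0.5, -3.0)
    outcome_sd: float = 0.8

    def __post_init__(self) -> None:
        sizes = self.sizes
        if min(sizes) < 2:
            raise ValueError("each group needs at least 2 samples")
        if self.linewidth <= 0:
            raise ValueError("linewidth must be positive")
        if self.noise_sd < 0 or self.dilution_sd < 0:
            raise ValueError("noise_sd and dilution_sd must be nonnegative")
        if self.points_per_ppm < 1:
            raise ValueError("points_per_ppm must be positive")

    @property
    def sizes(self) -> tuple[int, int]:
        if self.group_sizes is not None:
            return tuple(int(n) for n in self.group_sizes)  # type: ignore[return-value]
        return (self.n_per_group, self.n_per_group)


@dataclass
class SyntheticCohort:
    """A generated cohort plus its ground-truth generation record."""

    spectra: list[RawSpectrum]
    labels: np.ndarray
    continuous_outcome: np.ndarray
    truth: dict
    config: CohortConfig

    def __post_init__(self) -> None:
        n = len(self.spectra)
        if len(self.labels) != n or len(self.continuous_outcome) != n:
            raise ValueError("spectra, labels and continuous_outcome lengths differ")


def ppm_grid(config: CohortConfig) -> np.ndarray:
    """Acquisition axis: [-0.2, 10.2] ppm at ``points_per_ppm`` resolution."""
    n = int(round(10.4 * config.points_per_ppm)) + 1
    return np.linspace(-0.2, 10.2, n)


def simulate_spectrum(
    library: MetaboliteLibrary,
    concentrations: dict[str, float],
    config: CohortConfig,
    seed: int,
    sample_id: str = "",
) -> RawSpectrum:
    """Render one spectrum from a metabolite concentration mixture.

    Each metabolite contributes a Lorentzian of height equal to its
    concentration at every library shift (equal per-proton weight across a
    metabolite's resonances), plus a uniform baseline offset and Gaussian
    noise. Deterministic given ``seed``.
    """
    ppm = ppm_grid(config)
    intensity = np.zeros_like(ppm)
    hw2 = config.linewidth**2
    for name, conc in concentrations.items():
        if name not in library:
            raise KeyError(f"metabolite {name!r} not in library")
        conc = float(conc)
        if conc < 0:
            raise ValueError(f"negative concentration for {name!r}")
        if conc == 0.0:
            continue
        for shift in library.shifts(name):
            intensity += conc * hw2 / ((ppm - shift) ** 2 + hw2)
    rng = np.random.default_rng(seed)
    offset = rng.uniform(0.0, config.baseline_offset_range) if config.baseline_offset_range > 0 else 0.0
    intensity = intensity + offset
    if config.noise_sd > 0:
        intensity = intensity + rng.normal(0.0, config.noise_sd, size=ppm.size)
    return RawSpectrum(ppm, intensity, sample_id)


def simulate_cohort(
    config: CohortConfig,
    library: MetaboliteLibrary | None = None,
) -> SyntheticCohort:
    """Generate a two-group cohort with known group-mean log concentrations.

    Group 1 log-concentrations are shifted by ``effect_map`` relative to
    group 0; each sample's metabolite amounts (TMSP excepted — the reference
    is spiked at fixed concentration) are multiplied by a log-normal dilution
    factor. The ``truth`` record stores group-mean log concentrations, each
    sample's rendered (post-dilution) concentrations, and the per-sample
    render seed, so spectra can be reproduced exactly.
    """
    if library is None:
        library = default_library()
    unknown = set(config.effect_map) - set(library.names)
    if unknown:
        raise KeyError(f"effect_map metabolites not in library: {sorted(unknown)}")

    rng = np.random.default_rng(config.seed)
    n0, n1 = config.sizes
    metabolites = [m for m in library.names if m != REFERENCE]
    base = config.base_concentrations
    if base is None:
        base = DEFAULT_ABUNDANCES
    group_mean_log = {
        m: (
            float(np.log(base.get(m, 1.0))),
            float(np.log(base.get(m, 1.0)) + config.effect_map.get(m, 0.0)),
        )
        for m in metabolites
    }

    spectra: list[RawSpectrum] = []
    labels = np.repeat([0, 1], [n0, n1])
    sample_log_conc: list[dict[str, float]] = []
    rendered_conc: list[dict[str, float]] = []
    dilutions = np.empty(n0 + n1)
    seeds = np.empty(n0 + n1, dtype=np.int64)
    for i, g in enumerate(labels):
        log_conc = {
            m: group_mean_log[m][g] + rng.normal(0.0, config.log_conc_sd)
            for m in metabolites
        }
        dilution = float(np.exp(rng.normal(0.0, config.dilution_sd)))
        conc = {m: dilution * float(np.exp(v)) for m, v in log_conc.items()}
        conc[REFERENCE] = 1.0
        render_seed = int(rng.integers(0, 2**31 - 1))
        sid = f"S{i:03d}"
        spectra.append(simulate_spectrum(library, conc, config, render_seed, sid))
        sample_log_conc.append(log_conc)
        rendered_conc.append(conc)
        dilutions[i] = dilution
        seeds[i] = render_seed

    outcome = np.array(
        [config.outcome_means[g] + rng.normal(0.0, config.outcome_sd) for g in labels]
    )
    truth = {
        "group_mean_log_conc": group_mean_log,
        "sample_log_conc": sample_log_conc,
        "rendered_concentrations": rendered_conc,
        "dilution": dilutions,
        "render_seeds": seeds,
        "effect_map": dict(config.effect_map),
    }
    return SyntheticCohort(spectra, labels, outcome, truth, config)


#: The four-metabolite consensus signature of anti-TNF response, with the
#: reported directions in responders (up for histamine/glutamine/xanthurenic
#: acid, down for ethanolamine).
RESPONSE_SIGNATURE: dict[str, float] = {
    "histamine": +1.0,
    "glutamine": +1.0,
    "xanthurenic acid": +1.0,
    "ethanolamine": -1.0,
}


def response_effect_map(scale: float = 1.0) -> dict[str, float]:
    """Signed log-fold effects for the response signature, scaled."""
    return {m: scale * s for m, s in RESPONSE_SIGNATURE.items()}


#: Metabolites reported to rise under each drug among responders at 12
#: weeks. Expressed as group-1 (etanercept) effects relative to group 0
#: (infliximab): infliximab-elevated metabolites carry negative signs.
DRUG_CONTRAST_SIGNATURE: dict[str, float] = {
    "hippuric acid": -1.0,
    "citrate": -1.0,
    "lactic acid": -1.0,
    "choline": +1.0,
    "phenylacetic acid": +1.0,
    "urea": +1.0,
    "creatine": +1.0,
    "methylamine": +1.0,
}


def drug_contrast_effect_map(scale: float = 1.0) -> dict[str, float]:
    """Signed log-fold effects for the infliximab/etanercept contrast."""
    return {m: scale * s for m, s in DRUG_CONTRAST_SIGNATURE.items()}


def write_cohort(
    cohort: SyntheticCohort,
    outdir: str | Path,
    design: str = "response_at_baseline",
) -> Path:
    """Write a cohort as per-sample (ppm, intensity) CSVs + metadata + truth.

    ``design`` controls how the binary generation label is expressed in the
    metadata: as a responder flag at baseline, as a baseline/week-12
    timepoint pair per subject, or as the drug received (responders only).
    """
    outdir = Path(outdir)
    spectra_dir = outdir / "spectra"
    spectra_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cohort.config.seed + 1)

    rows = []
    for i, (spec, g, out) in enumerate(
        zip(cohort.spectra, cohort.labels, cohort.continuous_outcome)
    ):
        pd.DataFrame({"ppm": spec.ppm, "intensity": spec.intensity}).to_csv(
            spectra_dir / f"{spec.sample_id}.csv", index=False
        )
        das28_baseline = float(np.clip(rng.normal(6.2, 1.0), 4.0, 9.0))
        row = {
            "sample_id": spec.sample_id,
            "subject_id": f"P{i:03d}",
            "disease": "RA",
            "drug": "infliximab" if i % 2 == 0 else "etanercept",
            "timepoint": "baseline",
            "responder": int(g),
            "das28_baseline": das28_baseline,
            "das28_12mo": das28_baseline + float(out),
            "crp": float(np.round(np.exp(rng.normal(2.0, 0.8)), 3)),
            "acr": float(np.round(np.exp(rng.normal(-1.0, 0.9)), 4)),
        }
        if design == "baseline_vs_12week":
            # pair sample i of group 0 with sample i of group 1
            idx_in_group = i if g == 0 else i - int(np.sum(cohort.labels == 0))
            row["subject_id"] = f"P{idx_in_group:03d}"
            row["timepoint"] = "baseline" if g == 0 else "week12"
            row["responder"] = 1
        elif design == "drug_contrast":
            row["drug"] = "infliximab" if g == 0 else "etanercept"
            row["timepoint"] = "week12"
            row["responder"] = 1
        elif design != "response_at_baseline":
            raise ValueError(f"unknown design {design!r}")
        rows.append(row)
    pd.DataFrame(rows).to_csv(outdir / "metadata.csv", index=False)

    truth = {
        "group_mean_log_conc": cohort.truth["group_mean_log_conc"],
        "effect_map": cohort.truth["effect_map"],
        "render_seeds": [int(s) for s in cohort.truth["render_seeds"]],
        "dilution": [float(d) for d in cohort.truth["dilution"]],
    }
    (outdir / "truth.json").write_text(json.dumps(truth, indent=2, sort_keys=True))
    return outdir
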