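"""Synthetic depth-profile peak lists with known ground truth.

Emulates what a high-mass-resolving-power SIMS depth profile export
looks like after peak searching: each ground-truth ion sits at its
theoretical single-charge m/z perturbed by Gaussian ppm-scale mass
error, carries a per-scan intensity profile (an exponentially decaying
overlayer, a logistic substrate rise, or a constant background) with
multiplicative log-normal intensity noise, and is mixed with decoy
peaks at uniform random m/z that have no true composition. Decoys may
still be assignable by chance — that is realistic and intentional.

All randomness flows through one ``numpy`` generator seeded once; the
draw order is: per component (in list order), per formula (in list
order) first the m/z jitter then the per-scan intensity noise, then the
decoy count, decoy m/z values, and decoy intensity noise.

What this generator does *not* emulate: isotope envelopes, detector
saturation/dead-time, mass-axis drift within a profile, correlated
chemical background, or lateral (x, y) structure.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .chem import ion_mz, parse_formula
from .engine import AssignmentSet, SearchConstraints
from .peaklist import Peak, PeakList

__all__ = [
    "ComponentSpec",
    "NoiseSpec",
    "GroundTruth",
    "simulate_peaklist",
    "evaluate_assignment",
    "load_scenario",
    "bundled_scenario_path",
]


@dataclass(frozen=True)
class ComponentSpec:
    """One chemical component: a family of ion formulas sharing a depth
    behavior.

    ``shape`` is one of ``exp_decay`` (params: rate), ``logistic_rise``
    (params: midpoint, steepness) or ``constant``; shapes are evaluated
    on normalized depth x = scan/(n_scans-1) and scaled to unit maximum
    before multiplying by ``base_intensity``.
    """

    name: str
    formulas: tuple[str, ...]
    class_label: str = ""
    shape: str = "exp_decay"
    shape_params: dict = field(default_factory=dict)
    base_intensity: float = 1000.0

    def __post_init__(self) -> None:
        if self.base_intensity <= 0:
            raise ValueError(f"component {self.name!r}: base_intensity must be > 0")
        if self.shape not in ("exp_decay", "logistic_rise", "constant"):
            raise ValueError(f"component {self.name!r}: unknown shape {self.shape!r}")
        if self.shape == "exp_decay" and self.shape_params.get("rate", 1.0) <= 0:
            raise ValueError(f"component {self.name!r}: rate must be > 0")
        if (
            self.shape == "logistic_rise"
            and self.shape_params.get("steepness", 1.0) <= 0
        ):
            raise ValueError(f"component {self.name!r}: steepness must be > 0")

    def profile_shape(self, n_scans: int) -> np.ndarray:
        x = np.arange(n_scans) / max(n_scans - 1, 1)
        if self.shape == "exp_decay":
            shape = np.exp(-self.shape_params.get("rate", 3.0) * x)
        elif self.shape == "logistic_rise":
            mid = self.shape_params.get("midpoint", 0.5)
            steep = self.shape_params.get("steepness", 10.0)
            shape = 1.0 / (1.0 + np.exp(-steep * (x - mid)))
        else:
            shape = np.ones(n_scans)
        return shape / shape.max()


@dataclass(frozen=True)
class NoiseSpec:
    """Measurement-noise model for the simulator.

    mz_sigma_ppm : Gaussian sigma of the relative mass error, in ppm.
    intensity_sigma : sigma of the multiplicative log-normal per-scan noise.
    noise_peak_rate : expected (Poisson) number of decoy peaks.
    noise_mz_range : uniform m/z window decoys are drawn from.
    decoy_intensity_frac : decoy base intensity as a fraction of the
        weakest component's base intensity.
    """

    mz_sigma_ppm: float = 0.3
    intensity_sigma: float = 0.2
    noise_peak_rate: float = 0.0
    noise_mz_range: tuple[float, float] = (80.0, 1000.0)
    decoy_intensity_frac: float = 0.05

    def __post_init__(self) -> None:
        if min(self.mz_sigma_ppm, self.intensity_sigma, self.noise_peak_rate) < 0:
            raise ValueError("noise parameters must be >= 0")
        if self.noise_mz_range[0] <= 0 or self.noise_mz_range[1] <= self.noise_mz_range[0]:
            raise ValueError("noise_mz_range must be a positive increasing pair")


@dataclass
class GroundTruth:
    """Per-peak truth for generated (non-decoy) peaks, one row each."""

    records: pd.DataFrame  # peak_id, formula, component, theoretical_mz
    profiles: dict[str, np.ndarray]  # peak_id -> noiseless profile

    def formula_of(self, peak_id: str) -> str:
        row = self.records.loc[self.records["peak_id"] == peak_id, "formula"]
        if row.empty:
            raise KeyError(f"no truth for peak {peak_id!r}")
        return str(row.iloc[0])

    def write_tsv(self, path: str | Path) -> None:
        self.records.to_csv(path, sep="\t", index=False)


def simulate_peaklist(
    components: list[ComponentSpec],
    noise: NoiseSpec,
    n_scans: int,
    seed: int,
    charge: int = -1,
) -> tuple[PeakList, GroundTruth]:
    """Generate a depth-profile peak list plus its ground truth.

    Deterministic given ``seed``; with all noise terms zero and no
    decoys every peak m/z equals its theoretical ion m/z exactly and
    every profile equals shape x base_intensity.
    """
    if n_scans < 2:
        raise ValueError("n_scans must be >= 2")
    rng = np.random.default_rng(seed)
    polarity = "positive" if charge > 0 else "negative"

    peaks: list[Peak] = []
    truth_rows = []
    truth_profiles: dict[str, np.ndarray] = {}
    counter = 0
    for comp in components:
        shape = comp.profile_shape(n_scans)
        for ftext in comp.formulas:
            try:
                formula = parse_formula(ftext)
            except ValueError as exc:
                raise ValueError(
                    f"component {comp.name!r}: invalid formula {ftext!r} ({exc})"
                ) from exc
            theo = ion_mz(formula, charge)
            mz = theo * (1.0 + rng.normal(0.0, noise.mz_sigma_ppm) * 1e-6)
            clean = shape * comp.base_intensity
            if noise.intensity_sigma > 0:
                profile = clean * rng.lognormal(0.0, noise.intensity_sigma, n_scans)
            else:
                rng.lognormal(0.0, 1.0, n_scans)  # keep draw order fixed
                profile = clean.copy()
            counter += 1
            pid = f"p{counter:04d}"
            peaks.append(
                Peak(
                    id=pid,
                    mz=float(mz),
                    total_intensity=float(profile.sum()),
                    profile=profile,
                )
            )
            truth_rows.append(
                {
                    "peak_id": pid,
                    "formula": str(formula),
                    "component": comp.name,
                    "theoretical_mz": theo,
                }
            )
            truth_profiles[pid] = clean

    n_decoys = int(rng.poisson(noise.noise_peak_rate)) if noise.noise_peak_rate else 0
    if components:
        decoy_base = noise.decoy_intensity_frac * min(
            c.base_intensity for c in components
        )
    else:
        decoy_base = 1.0
    for _ in range(n_decoys):
        mz = float(rng.uniform(*noise.noise_mz_range))
        profile = decoy_base * rng.lognormal(0.0, max(noise.intensity_sigma, 0.1), n_scans)
        counter += 1
        peaks.append(
            Peak(
                id=f"p{counter:04d}",
                mz=mz,
                total_intensity=float(profile.sum()),
                profile=profile,
            )
        )

    pl = PeakList(
        peaks=peaks,
        polarity=polarity,
        n_scans=n_scans,
        metadata=f"synthetic scenario, seed={seed}",
    )
    truth = GroundTruth(
        records=pd.DataFrame(
            truth_rows, columns=["peak_id", "formula", "component", "theoretical_mz"]
        ),
        profiles=truth_profiles,
    )
    return pl, truth


def evaluate_assignment(truth: GroundTruth, aset: AssignmentSet) -> dict:
    """Score an assignment against ground truth.

    recall : fraction of truth peaks whose true formula appears among
        their candidates.
    precision : fraction of *unique* assignments (including any decoy
        peaks that happened to get one) that equal the true formula.
    unique_rate : fraction of assigned peaks with exactly one candidate.
    """
    truth_ids = set(truth.records["peak_id"])
    known_ids = set(aset.peak_ids)
    missing = truth_ids - known_ids
    if missing:
        raise ValueError(f"assignment lacks truth peaks: {sorted(missing)[:5]} ...")

    n_recalled = 0
    for pid in truth_ids:
        cands = aset.candidates.get(pid, [])
        if any(str(c.formula) == truth.formula_of(pid) for c in cands):
            n_recalled += 1
    recall = n_recalled / len(truth_ids) if truth_ids else 0.0

    n_unique = n_unique_correct = 0
    for pid, cands in aset.candidates.items():
        if len(cands) == 1:
            n_unique += 1
            if pid in truth_ids and str(cands[0].formula) == truth.formula_of(pid):
                n_unique_correct += 1
    precision = n_unique_correct / n_unique if n_unique else 0.0
    n_assigned = len(aset.candidates)
    return {
        "recall": recall,
        "precision": precision,
        "unique_rate": n_unique / n_assigned if n_assigned else 0.0,
        "n_truth": len(truth_ids),
        "n_assigned": n_assigned,
        "n_unique": n_unique,
    }


def load_scenario(path: str | Path):
    """Load a scenario config JSON.

    Returns ``(components, noise, n_scans, seed, charge, constraints)``
    where ``constraints`` is the bundled search box (or None).
    """
    with open(path) as fh:
        cfg = json.load(fh)
    components = [
        ComponentSpec(
            name=c["name"],
            formulas=tuple(c["formulas"]),
            class_label=c.get("class_label", ""),
            shape=c["shape"],
            shape_params=c.get("shape_params", {}),
            base_intensity=c.get("base_intensity", 1000.0),
        )
        for c in cfg["components"]
    ]
    noise = NoiseSpec(
        mz_sigma_ppm=cfg["noise"].get("mz_sigma_ppm", 0.0),
        intensity_sigma=cfg["noise"].get("intensity_sigma", 0.0),
        noise_peak_rate=cfg["noise"].get("noise_peak_rate", 0.0),
        noise_mz_range=tuple(cfg["noise"].get("noise_mz_range", (80.0, 1000.0))),
        decoy_intensity_frac=cfg["noise"].get("decoy_intensity_frac", 0.05),
    )
    constraints = (
        SearchConstraints.from_dict(cfg["constraints"]) if "constraints" in cfg else None
    )
    return (
        components,
        noise,
        int(cfg["n_scans"]),
        int(cfg.get("seed", 0)),
        int(cfg.get("charge", -1)),
        constraints,
    )


def bundled_scenario_path() -> Path:
    """Path to the bundled two-component demo scenario (sulfonate-like
    overlayer decaying over carbon-cluster substrate rising)."""
    from importlib import resources

    ref = resources.files("simsfilter.data") / "scenario_two_component.json"
    with resources.as_file(ref) as path:
        return Path(path)
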