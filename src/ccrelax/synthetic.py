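"""Synthetic decay-curve datasets with known ground truth.

Every fitting stage of the package is testable without downloads: this module
forward-simulates per-line multiplet intensities sampled once per second under
small-flip-angle read pulses (the experimental observable of a DDNP run) and
adds seeded Gaussian noise.  Ground truth and provenance are stored next to the
observations, never mixed with them.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .dynamics import FieldProfile, backpropagate_window, detection_train, thermal_state
from .relaxation import MECHANISMS, assemble_relaxation
from .spinsys import SpinSystem

__all__ = [
    "DecayCurveDataset",
    "generate_decay_curves",
    "generate_thermal_reference",
    "fixture_field_profile",
    "monoexponential_fixture",
]


@dataclass
class DecayCurveDataset:
    """Per-line multiplet intensities on a regular time grid.

    ``intensities`` has shape (n_scans, n_lines); ``ground_truth`` carries the
    generating combination and simulation settings, kept separate from the
    observations so that inverse tests cannot accidentally read the answer.
    """

    times: np.ndarray
    intensities: np.ndarray
    line_labels: list
    nucleus: str = "13C"
    flip_angles: dict = field(default_factory=dict)
    interval: float = 1.0
    noise_sigma: float = 0.0
    seed: int | None = None
    ground_truth: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    @property
    def n_scans(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_lines(self) -> int:
        return self.intensities.shape[1] if self.intensities.ndim == 2 else 0

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.intensities, columns=self.line_labels)
        df.insert(0, "time_s", self.times)
        return df

    def to_csv(self, path) -> None:
        """Write observations as CSV plus a JSON sidecar (ground truth + provenance)."""
        path = Path(path)
        self.to_frame().to_csv(path, index=False, float_format="%.12g")
        sidecar = {
            "nucleus": self.nucleus,
            "flip_angles": self.flip_angles,
            "interval_s": self.interval,
            "noise_sigma": self.noise_sigma,
            "seed": self.seed,
            "ground_truth": self.ground_truth,
            "provenance": self.provenance,
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1, sort_keys=True))

    @classmethod
    def from_csv(cls, path) -> "DecayCurveDataset":
        path = Path(path)
        df = pd.read_csv(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        lines = [c for c in df.columns if c != "time_s"]
        return cls(df["time_s"].to_numpy(), df[lines].to_numpy(), lines,
                   nucleus=meta["nucleus"], flip_angles=meta["flip_angles"],
                   interval=meta["interval_s"], noise_sigma=meta["noise_sigma"],
                   seed=meta["seed"], ground_truth=meta["ground_truth"],
                   provenance=meta["provenance"])


def _records_to_matrix(records, n_lines):
    labels = [f"line{k + 1}" for k in range(n_lines)]
    return np.array([[rec[lab] for lab in labels] for rec in records]), labels


def generate_decay_curves(system: SpinSystem, combo, R=None, pre_delay: float = 12.0,
                          B0: float = 11.7, flip_angles=None, interval: float = 1.0,
                          n_scans: int = 60, noise_sigma: float = 0.0,
                          seed: int | None = None, reference_polarization: float = 0.1,
                          rho_eq="thermal", mechanisms=None) -> DecayCurveDataset:
    """Forward-simulate a hyperpolarized decay-curve dataset with known truth."""
    if noise_sigma < 0:
        raise ValueError("noise sigma must be >= 0")
    if noise_sigma > 0 and seed is None:
        raise ValueError("a seed is required when noise is added")
    flip_angles = flip_angles or {"1H": 1.0, "13C": 30.0}
    mechanisms = tuple(mechanisms or MECHANISMS)
    if R is None:
        R = assemble_relaxation(system, B0, include=mechanisms)
    out = backpropagate_window(system, combo, pre_delay, B0, R=R,
                               reference_polarization=reference_polarization,
                               flip_angles=flip_angles, interval=interval,
                               n_scans=n_scans, rho_eq=rho_eq)
    n_lines = len(system.indices("1H")) + 1
    clean, labels = _records_to_matrix(out["scans"], n_lines)
    rng = np.random.default_rng(seed)
    noise = noise_sigma * np.max(np.abs(clean)) * rng.standard_normal(clean.shape) \
        if noise_sigma > 0 else 0.0
    combo_map = dict(combo) if isinstance(combo, dict) else {
        "Hz": combo.hz, "Cz": combo.cz, combo.kind: combo.imbalance}
    return DecayCurveDataset(
        out["scan_times"], clean + noise, labels, "13C", dict(flip_angles), interval,
        noise_sigma, seed,
        ground_truth={"combo": combo_map, "reference_polarization": reference_polarization,
                      "pre_delay_s": pre_delay, "B0_T": B0, "mechanisms": list(mechanisms),
                      "rho_eq": str(rho_eq)},
        provenance={"generator": "ccrelax.synthetic.generate_decay_curves",
                    "system": system.name or "".join(system.isotopes)})


def generate_thermal_reference(system: SpinSystem, B0: float = 11.7,
                               temperature: float = 298.0, n_scans: int = 16,
                               flip_angles=None, interval: float = 1.0,
                               noise_sigma: float = 0.0, seed: int | None = None,
                               mechanisms=None) -> DecayCurveDataset:
    """Steady-state multiplet of the Boltzmann state (the 1:3:3:1 / 1:2:1 baseline)."""
    if noise_sigma > 0 and seed is None:
        raise ValueError("a seed is required when noise is added")
    flip_angles = flip_angles or {"13C": 30.0}
    mechanisms = tuple(mechanisms or MECHANISMS)
    n_lines = len(system.indices("1H")) + 1
    labels = [f"line{k + 1}" for k in range(n_lines)]
    if n_scans == 0:
        return DecayCurveDataset(np.empty(0), np.empty((0, n_lines)), labels, "13C",
                                 dict(flip_angles), interval, noise_sigma, seed,
                                 ground_truth={"thermal": True, "B0_T": B0,
                                               "temperature_K": temperature},
                                 provenance={"generator":
                                             "ccrelax.synthetic.generate_thermal_reference"})
    R = assemble_relaxation(system, B0, include=mechanisms)
    rho0 = thermal_state(system, B0, temperature)
    times, records = detection_train(rho0, system, B0, R, flip_angles, interval,
                                     n_scans, rho_eq="thermal", temperature=temperature)
    clean, labels = _records_to_matrix(records, n_lines)
    rng = np.random.default_rng(seed)
    noise = noise_sigma * np.max(np.abs(clean)) * rng.standard_normal(clean.shape) \
        if noise_sigma > 0 else 0.0
    return DecayCurveDataset(times, clean + noise, labels, "13C", dict(flip_angles),
                             interval, noise_sigma, seed,
                             ground_truth={"thermal": True, "B0_T": B0,
                                           "temperature_K": temperature},
                             provenance={"generator":
                                         "ccrelax.synthetic.generate_thermal_reference"})


def monoexponential_fixture(t1: float, times=None, amplitude: float = 1.0) -> pd.DataFrame:
    """The bundled proton-decay fixture: a clean mono-exponential reference curve."""
    times = np.arange(0.0, 61.0) if times is None else np.asarray(times, dtype=float)
    return pd.DataFrame({"time_s": times,
                         "intensity": amplitude * np.exp(-times / t1)})


def fixture_field_profile(layout: str = "vienna", segments=None) -> FieldProfile:
    """Transfer field profiles for the two laboratory layouts.

    'vienna' (4 s total): pulsed solenoid (0.21 T), magnetic tunnel (0.57 T),
    second solenoid, and a sub-mT gap before the spectrometer bore.
    'paris' (5 s total): no solenoids; a longer low-field gap at the polarizer
    end, then the tunnel and the final gap.  'custom' requires ``segments``.
    """
    if layout == "vienna":
        return FieldProfile([(0.75, 0.21), (2.0, 0.57), (0.75, 0.21), (0.5, 0.0008)],
                            name="vienna")
    if layout == "paris":
        return FieldProfile([(1.0, 0.005), (3.0, 0.57), (1.0, 0.0008)], name="paris")
    if layout == "custom":
        if not segments:
            raise ValueError("custom layout requires segments [(duration_s, B0_T), ...]")
        return FieldProfile([(float(d), float(b)) for d, b in segments], name="custom")
    raise ValueError("layout must be 'vienna', 'paris' or 'custom'")
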