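"""Configuration objects for simulation and pipeline runs.

All tunables live here with recorded defaults; configs round-trip
losslessly through YAML/JSON so a run is fully described by one file
plus one integer seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

#: Canonical profile labels, in fixed state order for all 8x8 matrices.
PROFILE_LABELS = ("E1", "E2", "E3", "E4", "L1", "L2", "L3", "L4")

#: Stimulus categories and their threat status.
DEFAULT_CATEGORIES = {
    "snake": True,
    "spider": True,
    "butterfly": False,
    "rabbit": False,
}


def _concentrated_matrix(self_p: float, pulls: dict[int, float]) -> np.ndarray:
    """Row-stochastic 8x8 matrix: ``self_p`` on the diagonal, extra mass
    pulled toward the states in ``pulls``, remainder spread uniformly."""
    P = np.zeros((8, 8))
    for i in range(8):
        row = np.zeros(8)
        row[i] = self_p
        for s, p in pulls.items():
            row[s] += p
        rest = row == 0
        row[rest] = (1.0 - row.sum()) / rest.sum()
        P[i] = row
    return P


def default_transition_matrices() -> dict[str, np.ndarray]:
    """Per-arm generating transition matrices over the 8 profiles.

    The three regimes emulate the qualitative dynamics the analysis is
    built to detect: a rigid placebo chain concentrated on profile E1,
    an intermediate vasopressin chain with attractors at E3/L3, and a
    maximally flexible losartan chain.  Trigram block entropies of the
    three chains are ~7.68, ~7.82 and ~8.02 bits respectively.
    """
    idx = {lab: i for i, lab in enumerate(PROFILE_LABELS)}
    return {
        "PLC": _concentrated_matrix(0.50, {idx["E1"]: 0.09}),
        "AVP": _concentrated_matrix(0.48, {idx["E3"]: 0.05, idx["L3"]: 0.05}),
        "LT": _concentrated_matrix(0.46, {}),
    }


@dataclass
class SimConfig:
    """Parameters of the synthetic looming-task dataset.

    The factorial design is 5 aTTC levels x 4 stimulus categories x 2
    initial sizes = 40 cells; ``repetitions`` copies of each cell give
    the default 160 trials per subject over ``n_blocks`` blocks.
    """

    n_subjects_per_arm: int = 37
    arms: tuple[str, ...] = ("LT", "PLC", "AVP")
    screen_width_px: float = 1280.0
    initial_size_fracs: tuple[float, ...] = (0.20, 0.30)
    attc_levels: tuple[float, ...] = (3.0, 3.5, 4.0, 4.5, 5.0)
    categories: dict[str, bool] = field(
        default_factory=lambda: dict(DEFAULT_CATEGORIES))
    n_blocks: int = 2
    repetitions: int = 4

    # behavioural generator: jTTC = alpha_eff * aTTC**beta_eff * exp(eps)
    alpha_baseline: float = 1.5
    beta_baseline: float = 0.55
    alpha_effects: dict[str, float] = field(
        default_factory=lambda: {"arm:AVP": 0.3})
    beta_effects: dict[str, float] = field(
        default_factory=lambda: {"arm:LT": -0.15, "threat": -0.09,
                                 "sex:F": -0.167})
    noise_sd_log_jttc: float = 0.1

    # pupil generator
    sample_ms: float = 10.0
    baseline_ms: float = 300.0
    tonic_mm: float = 4.0
    tonic_offsets: dict[str, float] = field(
        default_factory=lambda: {"AVP": 0.2})
    # integrated score variances in ratio 62:18:7 (shares of the total
    # trace variance once ~13% observation noise is added)
    score_sds: tuple[float, float, float] = (0.315, 0.170, 0.106)
    score_mean_effects: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: {
            "arm:AVP": (0.0, 0.08, 0.0),
            "threat": (0.0, 0.06, 0.02),
        })
    ar1_coef: float = 0.3
    noise_sd: float = 0.144
    blink_rate: float = 0.5
    blink_dur_ms: tuple[float, float] = (100.0, 300.0)

    # state-sequence generator
    transition_matrices: dict[str, np.ndarray] = field(
        default_factory=default_transition_matrices)

    seed: int = 0

    # ------------------------------------------------------------------
    def __post_init__(self) -> None:
        self.transition_matrices = {
            k: np.asarray(v, dtype=float)
            for k, v in self.transition_matrices.items()
        }
        self.validate()

    def validate(self) -> None:
        if self.repetitions < 1 or self.repetitions != int(self.repetitions):
            raise ValueError("repetitions must be a positive integer")
        n_cells = (len(self.attc_levels) * len(self.categories)
                   * len(self.initial_size_fracs))
        if n_cells <= 0:
            raise ValueError("empty factorial design")
        for arm, P in self.transition_matrices.items():
            if P.shape != (len(PROFILE_LABELS),) * 2:
                raise ValueError(f"transition matrix for {arm}: bad shape")
            if (P < 0).any():
                raise ValueError(f"transition matrix for {arm}: negative entry")
            if not np.allclose(P.sum(axis=1), 1.0, atol=1e-12):
                raise ValueError(f"transition matrix for {arm}: rows must sum to 1")

    @property
    def n_cells(self) -> int:
        return (len(self.attc_levels) * len(self.categories)
                * len(self.initial_size_fracs))

    @property
    def trials_per_subject(self) -> int:
        return self.n_cells * self.repetitions

    # -- serialization --------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["transition_matrices"] = {
            k: v.tolist() for k, v in self.transition_matrices.items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        names = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - names
        if unknown:
            raise ValueError(f"unknown SimConfig fields: {sorted(unknown)}")
        for key in ("arms", "initial_size_fracs", "attc_levels", "score_sds",
                    "blink_dur_ms"):
            if key in d:
                d[key] = tuple(d[key])
        if "score_mean_effects" in d:
            d["score_mean_effects"] = {
                k: tuple(v) for k, v in d["score_mean_effects"].items()}
        return cls(**d)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        text = (json.dumps(self.to_dict(), indent=2)
                if path.suffix == ".json"
                else yaml.safe_dump(self.to_dict(), sort_keys=False))
        path.write_text(text)

    @classmethod
    def load(cls, path: str | Path) -> "SimConfig":
        path = Path(path)
        text = path.read_text()
        d = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.from_dict(d)


@dataclass
class RunConfig:
    """Pipeline-level configuration: stage toggles and analysis tunables."""

    sim: SimConfig = field(default_factory=SimConfig)
    out_dir: str = "loomdyn_out"
    seed: int = 0

    # stage toggles
    run_behavior: bool = True
    run_trajectory: bool = True
    run_fpca: bool = True
    run_profiles: bool = True
    run_dynamics: bool = True

    # preprocessing
    bin_ms: float = 10.0
    outlier_sd: float = 5.0
    plausible_mm: tuple[float, float] = (1.5, 9.0)
    max_interp_frac: float = 0.30
    min_trial_ms: float = 2300.0

    # trajectory / FPCA
    grid_size: int = 101
    n_basis: int = 20
    cum_share: float = 0.85
    min_share: float = 0.05

    # clustering
    k_range: tuple[int, int] = (2, 6)
    n_boot: int = 1000
    n_folds: int = 5

    # dynamics
    block_len: int = 3
    attractor_threshold: float = 0.45

    min_trials_fit: int = 10

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["sim"] = self.sim.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "sim" in d:
            d["sim"] = SimConfig.from_dict(d["sim"])
        for key in ("plausible_mm", "k_range"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        text = (json.dumps(self.to_dict(), indent=2)
                if path.suffix == ".json"
                else yaml.safe_dump(self.to_dict(), sort_keys=False))
        path.write_text(text)

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        d = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.from_dict(d)


def stage_seed(master_seed: int, stage: str) -> int:
    """Derive a reproducible per-stage seed from one master seed.

    Uses numpy's SeedSequence spawn-key mechanism keyed on the stage
    name, so any stage can be re-run in isolation with the same stream.
    """
    h = np.frombuffer(stage.encode(), dtype=np.uint8).astype(np.uint32)
    ss = np.random.SeedSequence([np.uint32(master_seed % (2**31))] + list(h))
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))
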