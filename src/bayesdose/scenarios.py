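"""Dose ladder, scenario truths, printed example datasets and trial-data simulation.

The design modelled here is an eight-arm phase II trial for severe traumatic
brain injury: one standard-of-care control arm plus seven active hyperbaric /
normobaric oxygen regimens. Each active regimen is summarised by a scalar dose
strength ``nu`` — daily oxygen toxicity units divided by 100 (OTU/100) — which
is the covariate every dose-response model in :mod:`bayesdose.models` works on.
The control has no defined OTU dose and is always modelled separately.

Dose indexing is 1..8 with index 1 the control.  (Some figure conventions
number the seven active arms 1..7; this package uses dose index 1..8
everywhere.)
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ARM_NAMES",
    "DOSE_STRENGTHS",
    "DoseLadder",
    "ScenarioTruth",
    "TrialDataset",
    "dose_ladder",
    "scenario_truth",
    "fixture_dataset",
    "allocate",
    "simulate_trial_data",
]

N_DOSES = 8

ARM_NAMES = (
    "Control (1.0 ATA)",
    "1.5 ATA",
    "2.0 ATA",
    "NBH (100% FiO2 at 1.0 ATA)",
    "2.5 ATA",
    "1.5 ATA + NBH",
    "2.0 ATA + NBH",
    "2.5 ATA + NBH",
)

#: OTU/100 dose strength per arm; nan marks the control, whose dose is undefined.
DOSE_STRENGTHS = (np.nan, 2.60, 4.17, 5.40, 5.92, 6.20, 7.76, 9.52)


@dataclass(frozen=True)
class DoseLadder:
    """The fixed eight-level dose ladder.

    Attributes
    ----------
    index : ndarray of int
        Dose indices 1..8 (1 = control).
    name : tuple of str
        Arm labels.
    strength : ndarray of float
        Effective dose strength ``nu_d`` in OTU/100; ``nan`` for the control.
    """

    index: np.ndarray = field(default_factory=lambda: np.arange(1, N_DOSES + 1))
    name: tuple = ARM_NAMES
    strength: np.ndarray = field(default_factory=lambda: np.array(DOSE_STRENGTHS))

    def __post_init__(self):
        s = np.asarray(self.strength, dtype=float)
        if s.shape != (N_DOSES,):
            raise ValueError("ladder must have 8 levels")
        if not np.all(np.diff(s[1:]) > 0):
            raise ValueError("active-dose strengths must be strictly increasing")
        object.__setattr__(self, "strength", s)

    @property
    def active_strength(self) -> np.ndarray:
        """Strengths for the active doses (indices 2..8)."""
        return self.strength[1:]

    def is_control(self, index: int) -> bool:
        return index == 1

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"dose_index": self.index, "name": list(self.name), "strength": self.strength}
        )


def dose_ladder() -> DoseLadder:
    """Return the trial's fixed dose ladder (control + seven active regimens)."""
    return DoseLadder()


@dataclass(frozen=True)
class ScenarioTruth:
    """A simulation truth: one true response probability per dose.

    ``correct_set`` holds the active doses whose true rate exceeds the
    control's; ``best_set`` the doses attaining the maximum true rate (empty
    when no dose beats the control).
    """

    name: str
    true_rate: np.ndarray
    correct_set: frozenset
    best_set: frozenset

    def __post_init__(self):
        r = np.asarray(self.true_rate, dtype=float)
        if r.shape != (N_DOSES,):
            raise ValueError("true_rate must have length 8")
        if np.any((r < 0) | (r > 1)):
            raise ValueError("true rates must lie in [0, 1]")
        object.__setattr__(self, "true_rate", r)
        expected = frozenset(d for d in range(2, N_DOSES + 1) if r[d - 1] > r[0])
        if self.correct_set != expected:
            raise ValueError("correct_set inconsistent with true rates")
        if self.correct_set and not self.best_set <= self.correct_set:
            raise ValueError("best_set must be contained in a nonempty correct_set")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"dose_index": np.arange(1, N_DOSES + 1), "true_rate": self.true_rate}
        )


def _truth(name, rates, best):
    rates = np.asarray(rates, dtype=float)
    correct = frozenset(d for d in range(2, N_DOSES + 1) if rates[d - 1] > rates[0])
    return ScenarioTruth(name, rates, correct, frozenset(best))


# Simulation truths. Large: monotone increase; NBH: only the four arms with
# added 100% normobaric oxygen respond; OverDose: response rises to a peak at
# d=5 then falls as toxicity dominates; Null: no dose effect (used for type I
# error calibration).
_SCENARIOS = {
    "Large": _truth("Large", (0.40, 0.59, 0.60, 0.61, 0.62, 0.63, 0.64, 0.65), {8}),
    "NBH": _truth("NBH", (0.40, 0.40, 0.40, 0.70, 0.40, 0.70, 0.70, 0.70), {4, 6, 7, 8}),
    "OverDose": _truth("OverDose", (0.40, 0.40, 0.50, 0.55, 0.70, 0.40, 0.35, 0.30), {5}),
    "Null": _truth("Null", (0.40,) * 8, set()),
}


def scenario_truth(name: str) -> ScenarioTruth:
    """Return a named simulation truth (``Large``, ``NBH``, ``OverDose``, ``Null``)."""
    try:
        return _SCENARIOS[name]
    except KeyError:
        raise ValueError(
            f"unknown scenario {name!r}; choose from {sorted(_SCENARIOS)}"
        ) from None


@dataclass(frozen=True)
class TrialDataset:
    """Per-arm binomial data for one trial: sample sizes ``n`` and successes ``y``."""

    n: np.ndarray
    y: np.ndarray

    def __post_init__(self):
        n = np.asarray(self.n, dtype=int)
        y = np.asarray(self.y, dtype=int)
        if n.shape != (N_DOSES,) or y.shape != (N_DOSES,):
            raise ValueError("n and y must have length 8")
        if np.any(n < 0) or np.any(y < 0) or np.any(y > n):
            raise ValueError("need 0 <= y_d <= n_d for every dose")
        object.__setattr__(self, "n", n)
        object.__setattr__(self, "y", y)

    @property
    def rate(self) -> np.ndarray:
        """Observed response rate per arm (nan where n=0)."""
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.n > 0, self.y / np.maximum(self.n, 1), np.nan)

    def to_frame(self, ladder: DoseLadder | None = None) -> pd.DataFrame:
        ladder = ladder or dose_ladder()
        return pd.DataFrame(
            {
                "dose_index": np.arange(1, N_DOSES + 1),
                "strength": ladder.strength,
                "n": self.n,
                "y": self.y,
            }
        )

    def to_csv(self, path_or_buf=None, ladder: DoseLadder | None = None):
        return self.to_frame(ladder).to_csv(path_or_buf, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "TrialDataset":
        df = df.sort_values("dose_index")
        return cls(df["n"].to_numpy(), df["y"].to_numpy())

    @classmethod
    def from_csv(cls, path_or_buf) -> "TrialDataset":
        if isinstance(path_or_buf, str) and "\n" in path_or_buf:
            path_or_buf = io.StringIO(path_or_buf)
        return cls.from_frame(pd.read_csv(path_or_buf))


# Hypothetical example datasets, one per qualitative dose-response shape, all
# under the n=200 allocation (39 control, 23 per active arm).
_FIXTURE_Y = {
    "LargeMonotone": (16, 8, 10, 11, 12, 14, 16, 18),
    "NBHOnly": (16, 8, 8, 18, 8, 18, 18, 18),
    "OverDose": (16, 8, 10, 12, 18, 12, 4, 2),
}


def fixture_dataset(name: str) -> TrialDataset:
    """Return one of the three printed example datasets.

    ``LargeMonotone`` rises monotonically with dose strength, ``NBHOnly``
    responds only at the four arms with added normobaric oxygen, and
    ``OverDose`` peaks at d=5 and collapses at the highest doses.
    """
    try:
        y = _FIXTURE_Y[name]
    except KeyError:
        raise ValueError(
            f"unknown fixture {name!r}; choose from {sorted(_FIXTURE_Y)}"
        ) from None
    return TrialDataset(n=allocate(200), y=np.array(y))


def allocate(total_n: int) -> np.ndarray:
    """Split ``total_n`` subjects: ~20% to control, the rest equally over 7 active arms.

    The control size starts at ``round(0.2 * total_n)`` and is decremented
    until the remainder is divisible by 7, which reproduces the trial's
    (39, 23, ..., 23) split at ``total_n=200``.
    """
    total_n = int(total_n)
    if total_n < N_DOSES:
        raise ValueError("total_n must allow at least one subject per arm")
    target = int(np.rint(0.2 * total_n))
    feasible = [c for c in range(1, total_n - 6) if (total_n - c) % 7 == 0]
    if not feasible:
        raise ValueError(f"cannot allocate total_n={total_n} with the 20%/equal-split rule")
    # nearest feasible control size; prefer the smaller one on ties (200 -> 39)
    control = min(feasible, key=lambda c: (abs(c - target), c))
    active = (total_n - control) // 7
    if active < 1:
        raise ValueError(f"cannot allocate total_n={total_n} with the 20%/equal-split rule")
    return np.array([control] + [active] * 7)


def simulate_trial_data(
    truth: ScenarioTruth,
    allocation: np.ndarray | None = None,
    seed: int | np.random.Generator | None = None,
) -> TrialDataset:
    """Draw one trial dataset: independent ``Binomial(n_d, P_d)`` counts per arm."""
    if allocation is None:
        allocation = allocate(200)
    allocation = np.asarray(allocation, dtype=int)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    y = rng.binomial(allocation, truth.true_rate)
    return TrialDataset(n=allocation, y=y)


def truth_to_yaml(truth: ScenarioTruth) -> str:
    """Serialise a scenario truth to YAML (name, per-dose rates, best set)."""
    import yaml

    return yaml.safe_dump(
        {
            "name": truth.name,
            "true_rate": [float(r) for r in truth.true_rate],
            "best_set": sorted(truth.best_set),
        },
        sort_keys=False,
    )


def truth_from_yaml(src) -> ScenarioTruth:
    """Load a scenario truth from a YAML string or open file."""
    import yaml

    cfg = yaml.safe_load(src)
    rates = np.asarray(cfg["true_rate"], dtype=float)
    return _truth(cfg.get("name", "custom"), rates, set(cfg.get("best_set", [])))
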