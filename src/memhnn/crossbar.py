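"""Cross-point synapse array and the modified half-bias learning scheme.

The array has one row line (top electrode, TE) per post-neuron and one
column line (bottom electrode, BE) per pre-neuron — 6 x 32 = 192 cells at
the default size.  Training a single feature code takes two phases:

* **Potentiation** — rows whose desired output is 1 are driven to V_L while
  columns carrying a '1' bit are driven to V_H; the targeted cells see
  BE − TE = V_H − V_L = +2 V and potentiate.  All other lines sit at the
  common-mode voltage V_CM so that no half-selected cell sees more than
  V_R = 1 V.
* **Depression** — the rival rows (desired 0 within the groups containing
  the code's class) are driven to V_H while '1' columns are driven to V_L;
  the targeted cells see −2 V and depress.

V_CM is taken as the midpoint of V_H = 5 V and V_L = 3 V, the unique choice
keeping every half-selected magnitude at or below the 1 V switching
threshold.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, List, Optional, Sequence, Tuple

import numpy as np

from . import device as dev
from .codes import FeatureCode, codes_matrix
from .decision import DEFAULT_GROUPING, PairGrouping, depression_vector, label_vector

__all__ = [
    "LearningConfig",
    "BiasPattern",
    "Crossbar",
    "init_crossbar",
    "assign_potentiation_bias",
    "assign_depression_bias",
    "apply_bias",
    "train",
    "row_currents",
]


@dataclass(frozen=True)
class LearningConfig:
    """Line voltages and training-loop settings of the half-bias scheme.

    ``depression_mode`` selects which cells the depression phase targets
    (the label data marks the desired-fire rows; everything else is a
    candidate for depression):

    * ``"losers_active"`` — every desired-0 row at columns where the code
      bit is 1 (the label complement un-learns active inputs; default);
    * ``"rival_active"`` — only the rival rows inside the two groups
      containing the code's class, at active columns;
    * ``"winner_inactive"`` — the desired rows at columns where the bit is 0;
    * ``"both"`` — ``rival_active`` plus ``winner_inactive``.
    """

    v_h: float = 5.0
    v_l: float = 3.0
    v_cm: float = 4.0
    pulses_per_phase: int = 1
    depression_pulses: Optional[int] = None  # None -> same as pulses_per_phase
    epochs: int = 20
    init_g: Optional[float] = None  # None -> midpoint of the device bounds
    depression_mode: str = "losers_active"

    def validate(self, params: dev.DeviceParams) -> None:
        if self.v_h - self.v_l <= params.v_switch:
            raise ValueError("v_h - v_l must exceed the switching threshold")
        if abs(self.v_h - self.v_cm) > params.v_switch + 1e-12:
            raise ValueError("|v_h - v_cm| must not exceed the switching threshold")
        if abs(self.v_cm - self.v_l) > params.v_switch + 1e-12:
            raise ValueError("|v_cm - v_l| must not exceed the switching threshold")
        if self.pulses_per_phase < 1 or self.epochs < 1:
            raise ValueError("pulses_per_phase and epochs must be >= 1")
        if self.depression_pulses is not None and self.depression_pulses < 1:
            raise ValueError("depression_pulses must be >= 1")
        if self.depression_mode not in (
            "losers_active",
            "rival_active",
            "winner_inactive",
            "both",
        ):
            raise ValueError(f"unknown depression_mode {self.depression_mode!r}")
        g0 = self.init_g if self.init_g is not None else params.g_mid
        if not params.g_min <= g0 <= params.g_max:
            raise ValueError(f"init_g = {g0} outside the conductance bounds")


@dataclass(frozen=True)
class BiasPattern:
    """Line voltages for one write phase: TE per row, BE per column."""

    te: np.ndarray
    be: np.ndarray
    phase: str  # "potentiation" | "depression"

    @property
    def cell_voltages(self) -> np.ndarray:
        """(rows x cols) matrix of BE − TE cell voltages."""
        return self.be[None, :] - self.te[:, None]


@dataclass
class Crossbar:
    """Grid of synapse conductances, rows = post-neurons, cols = pre-neurons."""

    g: np.ndarray  # (n_rows, n_cols) conductances in nA/V
    params: dev.DeviceParams = field(default_factory=dev.DeviceParams)

    def __post_init__(self):
        self.g = np.asarray(self.g, dtype=float)
        if self.g.ndim != 2:
            raise ValueError("conductance grid must be 2-D")
        if np.any(self.g < self.params.g_min) or np.any(self.g > self.params.g_max):
            raise ValueError("conductance outside device bounds")

    @property
    def n_rows(self) -> int:
        return self.g.shape[0]

    @property
    def n_cols(self) -> int:
        return self.g.shape[1]

    @property
    def n_cells(self) -> int:
        return self.g.size

    def copy(self) -> "Crossbar":
        return Crossbar(g=self.g.copy(), params=self.params)

    def write_text(self, path) -> None:
        header = (
            f"crossbar conductances (nA/V), rows=post-neurons cols=pre-neurons\n"
            f"g_min={self.params.g_min} g_max={self.params.g_max}"
        )
        np.savetxt(path, self.g, fmt="%.9g", header=header, delimiter="\t")

    @classmethod
    def read_text(cls, path, params: Optional[dev.DeviceParams] = None) -> "Crossbar":
        g = np.loadtxt(path, delimiter="\t")
        return cls(g=np.atleast_2d(g), params=params or dev.DeviceParams())


def init_crossbar(
    config: LearningConfig = LearningConfig(),
    params: dev.DeviceParams = dev.DeviceParams(),
    n_rows: int = 6,
    n_cols: int = 32,
) -> Crossbar:
    """Fresh array with every cell at the initial conductance (default: midpoint)."""
    config.validate(params)
    g0 = config.init_g if config.init_g is not None else params.g_mid
    return Crossbar(g=np.full((n_rows, n_cols), g0, dtype=float), params=params)


def _check_lengths(desired: np.ndarray, code: FeatureCode, n_rows: int, n_cols: int) -> None:
    if len(desired) != n_rows:
        raise ValueError(f"label vector length {len(desired)} != {n_rows} rows")
    if len(code) != n_cols:
        raise ValueError(f"feature code length {len(code)} != {n_cols} columns")


def assign_potentiation_bias(
    desired: Sequence[int],
    code: FeatureCode,
    config: LearningConfig = LearningConfig(),
) -> BiasPattern:
    """Line voltages that potentiate the desired rows at the active columns.

    Desired rows: TE = V_L; others V_CM.  Active ('1') columns: BE = V_H;
    others V_CM.  Targeted cells then see +2 V, everything else at most 1 V.
    """
    desired = np.asarray(desired, dtype=int)
    te = np.where(desired == 1, config.v_l, config.v_cm)
    be = np.where(code.array == 1, config.v_h, config.v_cm)
    return BiasPattern(te=te, be=be, phase="potentiation")


def assign_depression_bias(
    depress: Sequence[int],
    code: FeatureCode,
    config: LearningConfig = LearningConfig(),
    *,
    invert_bits: bool = False,
) -> BiasPattern:
    """Line voltages that depress the marked rows at the active columns.

    Marked rows: TE = V_H; others V_CM.  Active columns: BE = V_L; others
    V_CM — targeted cells see −2 V.  With ``invert_bits`` the *inactive*
    columns are driven instead (the ``winner_inactive`` depression variant).
    """
    depress = np.asarray(depress, dtype=int)
    bits = code.array
    if invert_bits:
        bits = 1.0 - bits
    te = np.where(depress == 1, config.v_h, config.v_cm)
    be = np.where(bits == 1, config.v_l, config.v_cm)
    return BiasPattern(te=te, be=be, phase="depression")


def apply_bias(
    xbar: Crossbar,
    bias: BiasPattern,
    pulses: int = 1,
    rng: Optional[np.random.Generator] = None,
) -> Crossbar:
    """Apply ``pulses`` identical pulses of the bias pattern to every cell in place."""
    if bias.te.shape != (xbar.n_rows,) or bias.be.shape != (xbar.n_cols,):
        raise ValueError("bias pattern dimensions do not match the array")
    v = bias.cell_voltages
    for _ in range(pulses):
        xbar.g = dev.update_conductance(xbar.g, xbar.params, v, rng=rng)
    return xbar


def _train_one_code(
    xbar: Crossbar,
    code: FeatureCode,
    grouping: PairGrouping,
    config: LearningConfig,
    rng: Optional[np.random.Generator],
) -> None:
    desired = label_vector(code.label, grouping)
    dep_pulses = (
        config.depression_pulses
        if config.depression_pulses is not None
        else config.pulses_per_phase
    )
    apply_bias(
        xbar, assign_potentiation_bias(desired, code, config), config.pulses_per_phase, rng
    )
    if config.depression_mode in ("losers_active", "rival_active", "both"):
        if config.depression_mode == "losers_active":
            depress = 1 - desired
        else:
            depress = depression_vector(code.label, grouping)
        apply_bias(
            xbar, assign_depression_bias(depress, code, config), dep_pulses, rng
        )
    if config.depression_mode in ("winner_inactive", "both"):
        apply_bias(
            xbar,
            assign_depression_bias(desired, code, config, invert_bits=True),
            dep_pulses,
            rng,
        )


def train(
    xbar: Crossbar,
    dataset: Sequence[FeatureCode],
    grouping: PairGrouping = DEFAULT_GROUPING,
    config: LearningConfig = LearningConfig(),
    rng: Optional[np.random.Generator] = None,
    stop_fn: Optional[Callable[[Crossbar, int], bool]] = None,
) -> Tuple[Crossbar, List[np.ndarray]]:
    """Supervised potentiation/depression training over the labelled dataset.

    Each epoch presents every code once, running the potentiation phase then
    the depression phase.  Returns the trained crossbar and a log of the
    per-row mean conductance after each epoch.  ``stop_fn(xbar, epoch)`` may
    end training early (used by the model layer to stop at 100 % training
    accuracy).
    """
    config.validate(xbar.params)
    if any(c.label is None for c in dataset):
        raise ValueError("all training codes must carry a class label")
    log: List[np.ndarray] = []
    for epoch in range(config.epochs):
        for code in dataset:
            _train_one_code(xbar, code, grouping, config, rng)
        log.append(xbar.g.mean(axis=1).copy())
        if stop_fn is not None and stop_fn(xbar, epoch):
            break
    return xbar, log


def row_currents(
    xbar: Crossbar, code: FeatureCode, v_read: float = 1.0
) -> np.ndarray:
    """Read current per row (nA): sum of g · v_read over the active columns."""
    if len(code) != xbar.n_cols:
        raise ValueError("feature code length does not match the array")
    if abs(v_read) > xbar.params.v_read + 1e-12:
        raise ValueError("read voltage outside the linear read regime")
    return xbar.g @ code.array * v_read
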