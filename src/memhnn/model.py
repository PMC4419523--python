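"""Model/Results interface tying the hardware simulator together.

:class:`MemristiveHNN` is constructed from labelled 32-bit feature codes
(or straight from an EEG dataset via :meth:`MemristiveHNN.from_eeg`), and
``fit()`` performs the two steps a hardware bring-up performs:

1. **Training** — the supervised potentiation/depression loop of the
   half-bias scheme, run until every training code is recognised or the
   epoch budget is exhausted.
2. **Comparator calibration** — the transimpedance gain of the LIF
   post-neurons is set from the trained array's read currents so that the
   firing-threshold current sits a safety fraction below the weakest
   class-labelled (winner) response on the training set.  Every class
   neuron then reliably fires on its own class, while recognition itself
   is decided by firing *order*: the decision logic latches as soon as one
   class has won two of the three pairwise groups, integration ends and
   the refractory phase begins.  On a correctly recognised input the two
   neurons representing its class fire first, so exactly two fire signals
   are generated — the measured two-of-six signature.

The returned :class:`HNNResults` carries the trained conductances, the
calibrated neuron parameters, the training history, and prediction /
scoring / summary methods.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import crossbar as xb
from . import neuron as nr
from .codes import CLASSES, FeatureCode, codes_matrix
from .decision import (
    DEFAULT_GROUPING,
    PairGrouping,
    classify,
    fired_count,
    label_vector,
    recognize,
)
from .device import DeviceParams

__all__ = ["MemristiveHNN", "HNNResults"]


class MemristiveHNN:
    """Single-layer memristive network: 32 pre-neurons, 6 LIF post-neurons.

    Parameters
    ----------
    train_codes : labelled feature codes used by ``fit``.
    grouping : pairing of the post-neurons into the three vowel comparisons.
    device_params, learning, neuron_params : hardware constants; defaults
        follow the documented device and line voltages.
    """

    def __init__(
        self,
        train_codes: Sequence[FeatureCode],
        grouping: PairGrouping = DEFAULT_GROUPING,
        device_params: Optional[DeviceParams] = None,
        learning: Optional[xb.LearningConfig] = None,
        neuron_params: Optional[nr.NeuronParams] = None,
    ):
        if not train_codes:
            raise ValueError("at least one training code is required")
        if any(c.label is None for c in train_codes):
            raise ValueError("training codes must be labelled")
        self.train_codes = list(train_codes)
        self.grouping = grouping
        self.device_params = device_params or DeviceParams()
        self.learning = learning or xb.LearningConfig()
        self.neuron_params = neuron_params or nr.NeuronParams()
        self.n_bits = len(train_codes[0])

    @classmethod
    def from_eeg(cls, dataset, feature_config=None, **kwargs) -> "MemristiveHNN":
        """Build the model from an EEG dataset via the feature pipeline.

        The extracted test codes and the pipeline log are attached as
        ``model.test_codes`` and ``model.pipeline_log``.
        """
        from .eeg import FeatureConfig, extract_pipeline

        train_codes, test_codes, log = extract_pipeline(
            dataset, feature_config or FeatureConfig()
        )
        model = cls(train_codes, **kwargs)
        model.test_codes = test_codes
        model.pipeline_log = log
        return model

    # ------------------------------------------------------------------
    def _labels_matrix(self) -> np.ndarray:
        return np.stack(
            [label_vector(c.label, self.grouping) for c in self.train_codes]
        ).astype(bool)

    def _calibrated_neuron(
        self, crossbar: xb.Crossbar, safety: float = 0.8
    ) -> Tuple[nr.NeuronParams, Dict]:
        """Comparator calibration from training-set read currents.

        The firing-threshold current is placed at ``safety`` times the
        smallest winner-row current observed on the training set, so every
        class neuron keeps firing on its own class despite the spread in
        code weights; rows well below the class responses (the depressed
        losers) saturate above the comparator threshold and never fire.
        """
        currents = crossbar.g @ codes_matrix(self.train_codes).T  # (rows, codes)
        win = self._labels_matrix().T
        i_win_min = float(currents[win].min())
        i_other_max = float(currents[~win].max())
        i_star = safety * i_win_min
        p = self.neuron_params
        window = 1.0 - np.exp(-p.t_integrate / p.tau)
        info = {
            "i_win_min": i_win_min,
            "i_other_max": i_other_max,
            "i_threshold": i_star,
            "separable": i_win_min > i_other_max,
        }
        if i_star <= 0:
            return p, info
        gain = p.fire_margin / (i_star * window)
        return replace(p, gain=gain), info

    def _accuracy(
        self, crossbar: xb.Crossbar, params: nr.NeuronParams, codes: Sequence[FeatureCode]
    ) -> float:
        correct = 0
        for code in codes:
            t_fire = nr.run_trial(crossbar, code, params).t_fire
            pred, _ = classify(t_fire, self.grouping)
            correct += pred == code.label
        return correct / len(codes)

    def fit(
        self,
        epochs: Optional[int] = None,
        rng: Optional[np.random.Generator] = None,
        calibrate: bool = True,
    ) -> "HNNResults":
        """Train the crossbar and calibrate the post-neurons.

        Training stops early once the calibrated network classifies every
        training code correctly.  ``rng`` only matters when the device's
        optional rate jitter is enabled.
        """
        learning = (
            self.learning if epochs is None else replace(self.learning, epochs=epochs)
        )
        crossbar = xb.init_crossbar(
            learning, self.device_params, self.grouping.n_neurons, self.n_bits
        )
        history: List[Dict] = []

        def stop(xbar: xb.Crossbar, epoch: int) -> bool:
            params, info = (
                self._calibrated_neuron(xbar) if calibrate else (self.neuron_params, {})
            )
            acc = self._accuracy(xbar, params, self.train_codes)
            history.append(
                {"epoch": epoch, "train_accuracy": acc, **info,
                 "mean_g_per_row": xbar.g.mean(axis=1).copy()}
            )
            return acc == 1.0

        crossbar, _ = xb.train(
            crossbar, self.train_codes, self.grouping, learning, rng=rng, stop_fn=stop
        )
        params, calibration = (
            self._calibrated_neuron(crossbar) if calibrate else (self.neuron_params, {})
        )
        return HNNResults(
            model=self,
            crossbar=crossbar,
            neuron_params=params,
            calibration=calibration,
            history=history,
        )


@dataclass
class HNNResults:
    """Fitted state of the memristive network."""

    model: MemristiveHNN
    crossbar: xb.Crossbar
    neuron_params: nr.NeuronParams
    calibration: Dict
    history: List[Dict]

    @property
    def n_epochs(self) -> int:
        return len(self.history)

    @property
    def train_accuracy(self) -> float:
        return self.history[-1]["train_accuracy"] if self.history else float("nan")

    # ------------------------------------------------------------------
    def trial(self, code: FeatureCode) -> nr.TrialResult:
        """Full integrator simulation (currents, fire times, traces) for one code."""
        return nr.run_trial(self.crossbar, code, self.neuron_params)

    def predict(self, codes: Sequence[FeatureCode]) -> List[Optional[str]]:
        """Predicted class per code (None = the decision logic abstained)."""
        out = []
        for code in codes:
            pred, _ = classify(self.trial(code).t_fire, self.model.grouping)
            out.append(pred)
        return out

    def score(self, codes: Sequence[FeatureCode]) -> float:
        """Fraction of labelled codes classified correctly (abstentions count as errors)."""
        preds = self.predict(codes)
        return float(np.mean([p == c.label for p, c in zip(preds, codes)]))

    def fire_counts(self, codes: Sequence[FeatureCode]) -> List[int]:
        """Fire signals generated per code, with the decision latch applied."""
        return [
            recognize(self.trial(code).t_fire, self.model.grouping)[2] for code in codes
        ]

    def confusion_matrix(self, codes: Sequence[FeatureCode]) -> Dict[str, Dict[str, int]]:
        """Nested counts: true class -> predicted class / 'abstain'."""
        labels = list(CLASSES) + ["abstain"]
        table = {c: {p: 0 for p in labels} for c in CLASSES}
        for code, pred in zip(codes, self.predict(codes)):
            table[code.label][pred if pred is not None else "abstain"] += 1
        return table

    def report(self, codes: Sequence[FeatureCode]) -> List[Dict]:
        """Per-trial record: prediction, per-group winners, fire times and counts.

        ``n_fired`` is the number of fire signals generated before the
        decision latched (the system's observable fire count);
        ``n_crossings`` counts every threshold crossing over the full
        integration window, latch ignored.
        """
        out = []
        for i, code in enumerate(codes):
            t_fire = self.trial(code).t_fire
            pred, winners, n_fired, t_decision = recognize(t_fire, self.model.grouping)
            out.append(
                {
                    "index": i,
                    "true": code.label,
                    "predicted": pred,
                    "correct": pred == code.label,
                    "group_winners": winners,
                    "t_fire": t_fire,
                    "t_decision": t_decision,
                    "n_fired": n_fired,
                    "n_crossings": fired_count(t_fire),
                }
            )
        return out

    def summary(self, test_codes: Optional[Sequence[FeatureCode]] = None) -> str:
        lines = [
            "Memristive HNN fit",
            "==================",
            f"array                 : {self.crossbar.n_rows} x {self.crossbar.n_cols}"
            f" = {self.crossbar.n_cells} cells",
            f"epochs run            : {self.n_epochs}",
            f"training accuracy     : {self.train_accuracy:.3f}",
            f"conductance range     : [{self.crossbar.g.min():.3f}, {self.crossbar.g.max():.3f}] nA/V",
        ]
        if self.calibration:
            lines += [
                f"firing threshold      : {self.calibration['i_threshold']:.2f} nA"
                f" (margin {self.calibration['i_win_min']:.2f} / {self.calibration['i_other_max']:.2f})",
                f"calibrated gain       : {self.neuron_params.gain:.5f} V/nA",
                f"train currents separable: {self.calibration['separable']}",
            ]
        if test_codes:
            acc = self.score(test_codes)
            n_ok = int(round(acc * len(test_codes)))
            lines.append(
                f"test accuracy         : {acc:.3f} ({n_ok}/{len(test_codes)})"
            )
        return "\n".join(lines)
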