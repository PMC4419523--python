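"""Plot helpers: integrator traces and device pulse-train response.

Matplotlib is imported lazily so headless library use stays light.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np

from .neuron import NeuronParams, TrialResult

__all__ = ["plot_traces", "plot_pulse_train"]


def plot_traces(
    result: TrialResult,
    params: NeuronParams = NeuronParams(),
    title: Optional[str] = None,
    path=None,
):
    """Six integrator outputs over the integrate + refractory phases.

    The comparator threshold and the reset level are drawn as horizontal
    guides; neurons that fired are marked at their crossing time.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4))
    t_ms = 1e3 * result.times
    for r in range(result.traces.shape[0]):
        (line,) = ax.plot(t_ms, result.traces[r], label=f"neuron {r}")
        if result.t_fire[r] is not None:
            ax.plot(1e3 * result.t_fire[r], params.v_th, "o", color=line.get_color())
    ax.axhline(params.v_th, ls="--", c="k", lw=0.8, label="V_TH")
    ax.axhline(params.v_reset, ls=":", c="gray", lw=0.8, label="reset")
    ax.axvline(1e3 * params.t_integrate, ls=":", c="gray", lw=0.8)
    ax.set_xlabel("time (ms)")
    ax.set_ylabel("integrator output (V)")
    if title:
        ax.set_title(title)
    ax.legend(ncol=2, fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_pulse_train(
    potentiation: Sequence[float], depression: Sequence[float], path=None
):
    """Conductance vs pulse number for identical potentiating/depressing pulses."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.5))
    n = np.arange(1, len(potentiation) + 1)
    ax.plot(n, potentiation, label="potentiation")
    ax.plot(n, depression, label="depression")
    ax.set_xlabel("pulse number")
    ax.set_ylabel("conductance (nA/V)")
    ax.legend()
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
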