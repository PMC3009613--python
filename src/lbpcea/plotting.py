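"""Optional diagnostic plots: CE plane, acceptability curve, EVPI curve."""

from __future__ import annotations

import pandas as pd

from .psa import CEACCurve


def plot_ce_plane(samples: pd.DataFrame, ax=None):
    """Scatter of incremental cost vs incremental QALYs over PSA draws."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.scatter(samples["delta_qaly"], samples["delta_cost"], s=4, alpha=0.3)
    ax.axhline(0, color="grey", lw=0.8)
    ax.axvline(0, color="grey", lw=0.8)
    ax.set_xlabel("Incremental QALYs")
    ax.set_ylabel("Incremental cost (KRW)")
    ax.set_title("Cost-effectiveness plane")
    return ax


def plot_ceac(curve: CEACCurve, ax=None):
    """Acceptability curves for both strategies against the threshold."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.plot(curve.lambdas, curve.p_collaborative, label="collaborative")
    ax.plot(curve.lambdas, curve.p_usual_care, label="usual care")
    ax.set_xlabel("Willingness to pay (KRW per QALY)")
    ax.set_ylabel("Probability cost-effective")
    ax.set_ylim(0, 1)
    ax.legend()
    ax.set_title("Cost-effectiveness acceptability curve")
    return ax


def plot_evpi(evpi: pd.DataFrame, ax=None):
    """Population EVPI against the threshold."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.plot(evpi["lambda"], evpi["population_evpi"])
    ax.set_xlabel("Willingness to pay (KRW per QALY)")
    ax.set_ylabel("Population EVPI (KRW)")
    ax.set_title("Expected value of perfect information")
    return ax
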