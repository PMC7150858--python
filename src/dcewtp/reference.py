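"""Published WTP-space mixed logit estimates for the drug-form DCE.

These are the reported population means and standard deviations of the
normally distributed willingness-to-pay contrasts (EUR per week), by
treatment scenario, from the Polish outpatient survey this package emulates.
They serve two roles:

* default ground truth for the synthetic-respondent generator, so simulated
  studies reproduce the published preference structure, and
* input to the worked examples (preferred configuration, attribute
  importance) that operate on the printed coefficient table itself.

The published cost row does not pin down the lognormal scale distribution
unambiguously, so the scale defaults (``mu = 0``, ``sigma = 0.5``; median
scale 1 utility per EUR) are a neutral, identifiable convention of this
package, not a published value.
"""

from __future__ import annotations

import numpy as np

#: contrast order matching the dummy-coding of :func:`dcewtp.design.build_attribute_scheme`
CONTRASTS = ("long_tablet", "capsule", "medium", "large", "yellow", "blue", "red")

#: per-scenario published estimates: mean, se(mean), sd, se(sd) — EUR per week
REFERENCE_ESTIMATES = {
    "chronic": {
        "mean":    np.array([0.46, 0.96, -2.63, -5.29, 0.67, -0.65, -1.11]),
        "se_mean": np.array([0.05, 0.06, 0.06, 0.13, 0.10, 0.06, 0.07]),
        "sd":      np.array([0.03, 0.35, 0.73, 2.34, 0.13, 0.01, 0.38]),
        "se_sd":   np.array([0.04, 0.07, 0.09, 0.30, 0.09, 0.06, 0.06]),
    },
    "short_term": {
        "mean":    np.array([2.41, 1.92, -2.58, -4.61, 1.40, 0.06, -0.33]),
        "se_mean": np.array([0.15, 0.17, 0.14, 0.09, 0.15, 0.09, 0.14]),
        "sd":      np.array([0.69, 0.59, 0.99, 2.11, 0.02, 0.06, 0.55]),
        "se_sd":   np.array([0.10, 0.09, 0.15, 0.11, 0.11, 0.07, 0.08]),
    },
}

#: neutral default for the lognormal scale alpha_i = exp(mu + sigma * xi)
DEFAULT_SCALE_MU = 0.0
DEFAULT_SCALE_SIGMA = 0.5


def reference_truth(scenario: str, scale_mu: float = DEFAULT_SCALE_MU,
                    scale_sigma: float = DEFAULT_SCALE_SIGMA):
    """Population truth for the simulator, built from the published table."""
    from .simulate import PopulationTruth

    ref = REFERENCE_ESTIMATES[scenario]
    return PopulationTruth(
        wtp_mean=ref["mean"].copy(),
        wtp_sd=ref["sd"].copy(),
        scale_mu=scale_mu,
        scale_sigma=scale_sigma,
    )


def reference_summary():
    """The published coefficient table as a :class:`dcewtp.wtp.WTPSummary`."""
    from .wtp import summary_from_table

    return summary_from_table(
        {s: REFERENCE_ESTIMATES[s] for s in ("chronic", "short_term")}
    )
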