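"""Published reference values for MMP1 interdomain dynamics and allostery.

These constants are experimental/simulation results reported in the
literature for MMP1 on different substrates.  They parameterize the
synthetic study conditions (the two-state simulations) and serve as
format/range fixtures; the MD-derived values (pose entropies, the
aSyn-specific residue list) depend on specific long MD trajectories and are
not desk-scale reproduction targets.
"""

from __future__ import annotations

from .telegraph import TwoStateParams

__all__ = [
    "TWO_STATE_CONDITIONS",
    "two_state_params",
    "ASYN_EXCLUSIVE_ALLOSTERIC_RESIDUES",
    "POSE_GLCM_ENTROPIES",
]

#: Measured two-state parameters (active MMP1, no ligand) per substrate:
#: Gaussian centers S1 < S2 and the autocorrelation decay rate k1+k2 (1/s).
#: Individual rates are not published; equal forward/backward rates are the
#: documented default, flagged in run logs.
TWO_STATE_CONDITIONS: dict[str, dict[str, float]] = {
    "asyn_active": {"S1": 0.46, "S2": 0.52, "rate_sum": 0.08},
    "collagen_active": {"S1": 0.44, "S2": 0.55, "rate_sum": 0.13},
    "fibrin_active": {"S1": 0.42, "S2": 0.51, "rate_sum": 0.08},
}


def two_state_params(condition: str, sigma: float = 0.03) -> TwoStateParams:
    """TwoStateParams for a published condition with equal rates.

    ``sigma`` is the per-state Gaussian observation-noise SD used for
    simulations (histogram widths are not published numerically; 0.03 gives
    histogram widths comparable to the published figures).
    """
    c = TWO_STATE_CONDITIONS[condition]
    half = c["rate_sum"] / 2.0
    return TwoStateParams(S1=c["S1"], S2=c["S2"], k1=half, k2=half,
                          sigma1=sigma, sigma2=sigma)


#: aSyn-specific allosteric residues of MMP1 (hemopexin domain, author
#: numbering, from published MD simulations of the aSyn-bound enzyme).
#: Shipped for format/range validation of fingerprint outputs.
ASYN_EXCLUSIVE_ALLOSTERIC_RESIDUES: dict[str, int] = {
    "K281": 281, "T283": 283, "G292": 292, "G327": 327, "L328": 328,
    "E329": 329, "R337": 337, "F343": 343, "G345": 345, "N346": 346,
    "Y348": 348, "G353": 353, "Q354": 354, "D363": 363, "Y365": 365,
    "S366": 366, "S367": 367, "F368": 368, "P371": 371, "R372": 372,
    "V374": 374, "K375": 375, "A379": 379, "F391": 391, "A394": 394,
    "R399": 399, "M414": 414, "F419": 419, "V426": 426, "C466": 466,
}

#: Published GLCM Shannon entropies (nats) of residue-correlation maps for
#: three aSyn-MMP1 binding poses — range fixtures, not reproduction targets.
POSE_GLCM_ENTROPIES: dict[str, float] = {
    "pose1": 3.07,
    "pose2": 3.28,
    "pose3": 3.07,
}
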