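"""The canonical table of the 12 analysis features.

Features 1-8 are local-peak amplitudes/latencies of the four post-onset ERP
deflections, computed on the condition-wise stimulus-locked ERP.  Feature 9
is prestimulus low-gamma band power on single trials (no baseline
correction).  Feature 10 is the peak amplitude of the reversal positivity
before a button press; 11 and 12 are pre-button alpha and gamma band power,
estimated on the trial average and on single trials respectively.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class FeatureSpec:
    id: int
    name: str
    lock: str                     # 'stimulus_on' or 'button'
    window_ms: tuple[float, float]
    kind: str                     # peak_amplitude | peak_latency | band_power
    polarity: str = "none"        # positive | negative | none
    band_hz: tuple[float, float] | None = None
    estimation: str = "on_average"  # on_average | single_trial_mean
    baseline: str = "standard"      # standard | none

    def __post_init__(self) -> None:
        if self.kind == "band_power":
            if self.band_hz is None:
                raise ValueError(f"feature {self.id}: band_power needs band_hz")
            if self.polarity != "none":
                raise ValueError(f"feature {self.id}: spectral features have no polarity")
        else:
            if self.band_hz is not None:
                raise ValueError(f"feature {self.id}: peak features have no band_hz")
            if self.polarity not in ("positive", "negative"):
                raise ValueError(f"feature {self.id}: peak features need a polarity")


FEATURES: tuple[FeatureSpec, ...] = (
    FeatureSpec(1, "amp_positivity", "stimulus_on", (100, 200), "peak_amplitude", "positive"),
    FeatureSpec(2, "lat_positivity", "stimulus_on", (100, 200), "peak_latency", "positive"),
    FeatureSpec(3, "amp_negativity", "stimulus_on", (200, 280), "peak_amplitude", "negative"),
    FeatureSpec(4, "lat_negativity", "stimulus_on", (200, 280), "peak_latency", "negative"),
    FeatureSpec(5, "amp_frontoparietal_positivity", "stimulus_on", (280, 400), "peak_amplitude", "positive"),
    FeatureSpec(6, "lat_frontoparietal_positivity", "stimulus_on", (280, 400), "peak_latency", "positive"),
    FeatureSpec(7, "amp_late_positivity", "stimulus_on", (400, 600), "peak_amplitude", "positive"),
    FeatureSpec(8, "lat_late_positivity", "stimulus_on", (400, 600), "peak_latency", "positive"),
    FeatureSpec(9, "low_gamma_pre_onset", "stimulus_on", (-200, -50), "band_power",
                band_hz=(26, 40), estimation="single_trial_mean", baseline="none"),
    FeatureSpec(10, "amp_reversal_positivity", "button", (-300, -200), "peak_amplitude", "positive"),
    FeatureSpec(11, "alpha_pre_button", "button", (-1000, 0), "band_power",
                band_hz=(8, 13), estimation="on_average"),
    FeatureSpec(12, "gamma_pre_button", "button", (-1000, 0), "band_power",
                band_hz=(26, 60), estimation="single_trial_mean"),
)

FEATURE_BY_ID = {f.id: f for f in FEATURES}
ONSET_FEATURES = tuple(f for f in FEATURES if f.lock == "stimulus_on")
BUTTON_FEATURES = tuple(f for f in FEATURES if f.lock == "button")
FEATURE_NAMES = {f.id: f.name for f in FEATURES}
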