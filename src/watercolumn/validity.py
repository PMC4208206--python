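"""Shared validity rules for retrieved bottom reflectance.

One configuration object holds the three exclusion rules applied to every
retrieval, so the correctors and the benchmark agree bit-for-bit:

* ``rho_b_range``: retrieved albedo outside the open interval (0, 1) is
  physically invalid (``out_of_range``);
* ``exponential_threshold``: when the bottom-path attenuation factor falls
  below this value the inversion amplifies noise explosively
  (``exponential_regime``; default 0.0002);
* ``min_contribution_pct``: wavelengths where the bottom contributes less
  than this percentage of the surface signal carry no usable bottom
  information (``low_contribution``; default 0.5%).
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["ValidityConfig", "DEFAULT_VALIDITY", "FLAGS"]

#: Flag names, also used as bit positions in raster flag bands.
FLAGS = ("out_of_range", "low_contribution", "exponential_regime", "deep_exceeds_signal")


@dataclass(frozen=True)
class ValidityConfig:
    min_contribution_pct: float = 0.5
    exponential_threshold: float = 0.0002
    rho_b_range: tuple[float, float] = (0.0, 1.0)

    def __post_init__(self) -> None:
        if self.min_contribution_pct <= 0 or self.exponential_threshold <= 0:
            raise ValueError("validity thresholds must be positive")
        lo, hi = self.rho_b_range
        if not lo < hi:
            raise ValueError("rho_b_range must be an increasing interval")


DEFAULT_VALIDITY = ValidityConfig()
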