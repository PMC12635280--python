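"""Physical constants and conversion factors used across the pipeline."""

from __future__ import annotations

import numpy as np

#: Reduced gyromagnetic ratio of the proton, MHz/T.
GAMMA_BAR_MHZ_PER_T = 42.577

#: Gadolinium-class longitudinal relaxivity, s^-1 mM^-1.
R1_RELAXIVITY = 3.6


def larmor_hz(b0_tesla: float) -> float:
    """Proton Larmor frequency in Hz at field strength ``b0_tesla``."""
    return GAMMA_BAR_MHZ_PER_T * 1e6 * float(b0_tesla)


def kappa_static_dephasing(b0_tesla: float) -> float:
    """Static-dephasing constant kappa, s^-1 per ppm of source susceptibility.

    Under the static-dephasing regime for randomly placed spherical
    perturbers, the reversible relaxation rate contributed by a source of
    volume susceptibility ``|chi|`` (ppm) is ``R2' = kappa * |chi|`` with

        kappa = (2*pi / (9*sqrt(3))) * gamma_bar * B0 * 1e-6.

    At 3 T this is about 51.5 s^-1/ppm.
    """
    return (2.0 * np.pi / (9.0 * np.sqrt(3.0))) * larmor_hz(b0_tesla) * 1e-6
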