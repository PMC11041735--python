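"""Shared index and unit conventions.

All sample-window definitions are 1-based inclusive, matching the
acquisition convention in which the first 176 samples of each 400-sample
optoacoustic transient precede the arrival of the acoustic pulse (used for
DC-offset estimation) and samples 176..400 contain the signal (used for the
signal-energy summary).  The one-sample overlap at 176 is intentional and
kept as defined.  Every module must take its windows from here.
"""

# 1-based inclusive windows on the transient sample axis
DC_WINDOW = (1, 176)
ENERGY_WINDOW = (176, 400)

#: minimum transient length so that both windows exist
MIN_TRANSIENT_SAMPLES = 400


def dc_slice() -> slice:
    """0-based slice for the DC-offset window (samples 1..176)."""
    return slice(DC_WINDOW[0] - 1, DC_WINDOW[1])


def energy_slice() -> slice:
    """0-based slice for the signal-energy window (samples 176..400)."""
    return slice(ENERGY_WINDOW[0] - 1, ENERGY_WINDOW[1])


# Tunable quantum-cascade-laser emission limits, cm^-1 (with margin for the
# +0.55 cm^-1 grid anchoring of the instrument wavenumber tables).
WAVENUMBER_MIN = 908.0
WAVENUMBER_MAX = 2933.0

#: default raster step size, micrometres
DEFAULT_STEP_UM = 5.0

#: default pulses averaged per imaging acquisition
DEFAULT_N_AVERAGES = 50

#: dark-noise peak-to-peak amplitude of the detection chain, mV, measured
#: with the excitation beam blocked (at the default 50-pulse averaging)
DARK_NOISE_PTP_MV = 1.3
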