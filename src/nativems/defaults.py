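"""Single home for the headline filter thresholds.

Every stage that applies one of these cuts imports it from here, so each
threshold has exactly one definition and reports can echo it verbatim.
"""

#: Peaks below this signal-to-noise ratio are discarded during peak picking.
SN_THRESHOLD: float = 3.0

#: Maximum percent mass error (100*|M_exp - M_theo|/M_theo) for an
#: experimental mass to be assigned to a theoretical composition.
MAX_PCT_ERROR: float = 0.1

#: A detected species whose relative intensity is strictly below this
#: fraction of the base peak is classed "low_abundant".
LOW_ABUNDANCE_FRAC: float = 0.05

#: Proton mass in Da; the only adducting species modelled.
PROTON_MASS: float = 1.00728

#: Default acquisition m/z window.
MZ_WINDOW: tuple[float, float] = (1000.0, 8000.0)

#: Default resolving power (FWHM = m/z / resolution).
RESOLUTION: float = 15000.0
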