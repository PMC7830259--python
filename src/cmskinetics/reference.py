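"""Published reference values for the CMS acidic-hydrolysis study.

These constants define the study conditions the synthetic-data generator
emulates and the worked examples reproduce: the fitted rate constants of the
accelerated hydrolysis experiments (0.5 M sulfuric acid), the small reverse
rates of the reversible model, and the LC-MS calibration designs for
colistin A (CSA), colistin B (CSB) and the prodrug (CMS).
"""

from __future__ import annotations

#: Forward rate constants (min^-1) fitted by full-course reversible-model
#: simulation at each accelerated temperature (deg C).
FORWARD_RATE_CONSTANTS = {40.0: 0.0146, 50.0: 0.0709, 60.0: 0.4485}

#: Reverse rate constants k(-1) (min^-1) from the same fits; small and with
#: no temperature trend.
REVERSE_RATE_CONSTANTS = {40.0: 2.2e-3, 50.0: 3.54e-3, 60.0: 2.11e-3}

#: 20 deg C verification experiment: the rate constant predicted by the
#: Arrhenius extrapolation as tabulated (4 d.p.), and the experimentally
#: observed value.
VERIFICATION_TEMPERATURE_C = 20.0
K20_TABULATED = 0.0003
K20_OBSERVED = 0.0004

#: CMS calibration design: 7 levels, ug/mL, quadratic response.
CMS_LEVELS = (2.0, 6.0, 8.0, 12.0, 16.0, 20.0, 22.0)
#: Total-colistin levels hydrolysed from the upper 6 CMS levels; CSA/CSB
#: levels follow from the 30.1 : 69.9 mass split.
CS_TOTAL_LEVELS = (6.0, 8.0, 12.0, 16.0, 20.0, 22.0)

#: Published global calibration coefficients, intercept-first
#: (response = c0 + c1*x [+ c2*x^2]).
CSA_CURVE_COEFFS = (-195.3, 130.1)
CSB_CURVE_COEFFS = (-372.8, 125.2)
CMS_CURVE_COEFFS = (131.6, 20.97, 1.425)
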