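"""Score vulnerability, classify quadrants, measure group representation.

Four hand-placed tracts illustrate the Euclidean vulnerability score
V = sqrt((AC - AC_min)^2 + (WHP - WHP_min)^2) and the A-D quadrant scheme,
then representation ratios show which group over-occupies which quadrant.
"""

import pandas as pd

import fire_equity as fe

params = fe.VulnerabilityParams(ac_min=0.0, whp_min=0.0, ac_split=0.5, whp_split=0.5)
records = pd.DataFrame({
    "tract_id": ["t1", "t2", "t3", "t4"],
    "ac": [0.1, 0.9, 0.1, 0.9],
    "whp": [0.9, 0.9, 0.1, 0.1],
})
records["v"] = fe.compute_vulnerability(records["ac"], records["whp"], params)
records["quadrant"] = fe.assign_quadrant(records["ac"], records["whp"], params)
print(records.to_string(index=False))
print()
print("B (high hazard, high adaptive deficit) is the most vulnerable corner;")
print("C (moderate hazard, low deficit) the most secure.")

table = pd.DataFrame({
    "tract_id": ["t1", "t2", "t3", "t4"],
    "pop_total": [1000, 1000, 1000, 1000],
    "pop_g1": [100, 600, 100, 200],
    "pop_g2": [900, 400, 900, 800],
})
rep = fe.representation_ratios(records, table, ["pop_g1", "pop_g2"])
print()
print(rep.to_string(index=False))
print()
print("ratio = share of a group's total population living in the quadrant;")
print("a ratio above expected_share flags over-representation there.")
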