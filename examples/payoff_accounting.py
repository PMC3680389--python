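"""Exact accounting of one group-round and the end-of-session settlement.

Builds a single round by hand: one free-rider among three full contributors,
then two punishment points against the free-rider, then the ECU-to-currency
settlement over a short session.
"""

import numpy as np

from normpgg import GameConfig, RoundLedger, apply_punishment, settle_experiment, stage1_payoffs

cfg = GameConfig()  # endowment 20, MPCR 0.4, groups of 4, 1:3 punishment costs

contributions = (0, 20, 20, 20)
ledger = RoundLedger.empty(round=1, contributions=contributions, group_size=4)
ledger.stage1 = stage1_payoffs(contributions, cfg)
print("contributions:", contributions)
print("stage-1 payoffs:", ledger.stage1)
print("  -> the free-rider keeps the endowment plus 0.4 * 60 = 44 ECU;")
print("     each contributor gets 0.4 * 80 = 24 ECU from the group account.")

ledger.points[1, 0] = 2  # member 1 assigns 2 punishment points to the free-rider
apply_punishment(ledger, cfg)
print("\nafter punishment (2 points, sender pays 1 ECU each, target loses 3 each):")
print("final payoffs:", ledger.final)
print("group ECU destroyed:", ledger.stage1.sum() - ledger.final.sum(),
      "(= (1+3) * points)")

euros = settle_experiment([ledger], cfg)
print("\nsettlement after this one round (200 ECU show-up, 40 ECU per unit):")
print("currency per member:", np.round(euros, 3))
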