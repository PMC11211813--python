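"""The PU risk estimators on a small batch, by hand.

Shows the closed-form values at zero logits (every component is ln 2), the
clamped nnPU combination, and the difference between the sigmoid and the
pairwise-ranking unlabeled risks on a separated batch.
"""

import numpy as np

from pufun import nnpu_class_risk, ranking_unlabeled_risk, risk_components

labels = np.array([1, 1, 0, 0, 0, 0])  # 2 labeled positives, 4 unlabeled

# all-zero logits: sigmoid(0)=0.5 makes every component ln 2 = 0.6931
zeros = np.zeros(6)
rp_plus, rp_minus, ru_sig = risk_components(zeros, labels)
ru_rank = ranking_unlabeled_risk(zeros, labels)
print(f"zero logits: RP+={rp_plus:.4f} RP-={rp_minus:.4f} "
      f"RU-(sigmoid)={ru_sig:.4f} RU-(ranking)={ru_rank:.4f}")

value, clamped = nnpu_class_risk(rp_plus, rp_minus, ru_sig, pi=0.2, beta=0.0)
print(f"nnPU risk (pi=0.2, beta=0): {value:.6f}  clamp active: {clamped}")
value, clamped = nnpu_class_risk(rp_plus, rp_minus, ru_rank, pi=0.2, beta=0.02)
print(f"nnPU ranking risk (pi=0.2, gamma=0.1): {value:.6f}")

# a well-separated batch: positives high, unlabeled low
sep = np.array([4.0, 3.0, -3.0, -4.0, -3.5, -2.5])
_, _, ru_sig = risk_components(sep, labels)
ru_rank = ranking_unlabeled_risk(sep, labels)
print(f"separated batch: RU-(sigmoid)={ru_sig:.4f} RU-(ranking)={ru_rank:.4f}")

# shifting every logit changes the sigmoid risk but not the ranking risk
_, _, ru_sig_shift = risk_components(sep + 5.0, labels)
ru_rank_shift = ranking_unlabeled_risk(sep + 5.0, labels)
print(f"after +5 shift:  RU-(sigmoid)={ru_sig_shift:.4f} "
      f"RU-(ranking)={ru_rank_shift:.4f}")
# The ranking risk only cares that positives outrank unlabeled samples.
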