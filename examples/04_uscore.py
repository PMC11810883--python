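"""The uncertainty score on a worked example.

Filters pixels by their normalized uncertainty at tau = 1..100, traces the
filtered DSC / FTP / FTN curves, and combines their AUCs into the U-score:
(AUC1 + (1-AUC2) + (1-AUC3)) / 3.  Confident-correct and uncertain-incorrect
predictions raise the score.
"""

import numpy as np

from sphereseg import BinaryMask, UncertaintyMap, uscore, uscore_curves

rng = np.random.default_rng(5)
gt = np.zeros((32, 32), np.uint8)
gt[8:24, 10:26] = 1
pred = gt.copy()
pred[8:24, 24:27] = 1 - pred[8:24, 24:27]  # over/under-segmentation at one edge

# uncertainty high exactly on the erroneous rim, low elsewhere
norm = np.full((32, 32), 5.0)
norm[pred != gt] = 85.0
unc = UncertaintyMap(entropy=norm / 100 * np.log(2), normalized=norm,
                     value_bins=2, support=25)

curves = uscore_curves(BinaryMask(pred), BinaryMask(gt), unc)
report = uscore(curves)
print(f"unfiltered DSC          = {curves.dsc_curve[-1]:.3f}")
print(f"DSC at tau=50 (filtered)= {curves.dsc_curve[49]:.3f}  <- errors removed")
print(f"AUC1 (DSC curve)        = {report.auc1:.3f}")
print(f"AUC2 (FTP), AUC3 (FTN)  = {report.auc2:.3f}, {report.auc3:.3f}")
print(f"U-score                 = {report.u_score:.3f}")
print("(flagging exactly the wrong pixels as uncertain yields a high U-score)")
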