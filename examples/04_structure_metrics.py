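"""Structure-similarity metrics on toy backbones.

Builds ideal helices, applies rigid motions and noise, and evaluates
RMSD (with Kabsch superposition), superposition-free RMSPD, and the
length-normalized TM-score.
"""

import numpy as np
from scipy.spatial.transform import Rotation

from hpct import rmsd, rmspd, tm_d0, tm_score
from hpct.synthetic import helix_coords

rng = np.random.default_rng(0)
a = helix_coords(40)

rot = Rotation.random(rng=rng).as_matrix()
moved = a @ rot.T + np.array([10.0, -5.0, 3.0])
print("rigid copy:   RMSD %.2e A (0 after superposition), RMSPD %.2e A, TM %.3f"
      % (rmsd(a, moved), rmspd(a, moved), tm_score(a, moved)))

for sigma in (0.5, 1.5, 4.0):
    noisy = a + sigma * rng.standard_normal(a.shape)
    print("noise %.1f A:  RMSD %5.2f A, RMSPD %5.2f A, TM %.3f"
          % (sigma, rmsd(a, noisy), rmspd(a, noisy), tm_score(a, noisy)))
# TM-score decreases with noise; d0(40) = %.3f sets the distance scale at
# which residue deviations stop counting as "similar".
print("d0(40) = %.3f A" % tm_d0(40))
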