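"""Where the reconstruction loses volume: contour placement at the caps.

Reconstructed volumes are compared to reference volumes with Bland-Altman
statistics at two contour placements: the default (outermost contours half
a voxel inside the surface ends) and an interior placement (1.5 voxels
inside, emulating contours distributed at regular intervals over the
structure's width).  Interior placement truncates the apical caps, giving a
systematic negative mean difference — the reconstruction's volume
underestimation mechanism.
"""

from sparsesurf import FairingParams
from sparsesurf.experiments import run_sparse_experiment, volume_bias_experiment
from sparsesurf.phantoms import generate_cohort

cohort = generate_cohort(12, seed=42)
params = FairingParams(n_contours=10)

default = run_sparse_experiment(cohort, params).bland_altman
interior = volume_bias_experiment(cohort, params, end_margin_voxels=1.5)

for name, ba in (("default margin (0.5 voxel)", default),
                 ("interior margin (1.5 voxels)", interior)):
    print(f"{name}:")
    print(f"  mean difference {ba.mu_diff:+.3f} mL (SD {ba.sd:.3f}, "
          f"SE {ba.se:.3f}, p = {ba.p_value:.2g})")
    print(f"  95% limits of agreement [{ba.loa_lower:+.3f}, {ba.loa_upper:+.3f}] mL")
# A negative mean difference says the reconstruction is systematically
# smaller than the reference; interior contour placement misses the caps.
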