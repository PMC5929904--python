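"""Fit a DCM to a synthetic two-condition dataset and read the posterior.

Generates one calibrated 25 dB SNR dataset (forward connection modulated by
0.5, backward by 0.8 between conditions), inverts the true FB model with
the adaptive scheme, and prints the recovered modulation gains and
conduction delays with 90% credibility intervals.  Recovered values close
to the generative ones (0.5, 0.8, 16 ms) demonstrate parameter
identifiability at this noise level.
"""

import numpy as np

from delaydcm import (DCM, ERPParameters, FitControls, SolverOptions,
                      default_priors, generate_dataset, vb_invert)
from delaydcm.experiments import model_variant, sim1_network, sim1_parameters

grid = np.arange(0.0, 401.0, 1.0)
dataset = generate_dataset(sim1_network(16.0), sim1_parameters(),
                           SolverOptions(rel_tol=1e-3), snr_db=25.0,
                           seed=42, t_grid=grid)

template = model_variant(sim1_network(16.0), "FB")
dcm = DCM(template, ERPParameters(),
          SolverOptions(scheme="rk", rel_tol=1e-2, max_step=2.0))
priors = default_priors(template)
post = vb_invert(dataset, dcm, priors, FitControls(max_iter=32))

print(f"converged after {post.n_iter} iterations, "
      f"F = {post.free_energy:.1f} "
      f"(accuracy {post.accuracy:.1f}, complexity {post.complexity:.1f})")
for name, template_value, truth in (
        (("b", "forward", 1, 0), 1.0, 0.5),
        (("b", "backward", 0, 1), 1.0, 0.8),
        (("delay", 1, 0), 16.0, 16.0),
        (("delay", 0, 1), 16.0, 16.0)):
    lo, hi = post.credible_interval(name, template_value)
    est = post.natural(name, template_value)
    print(f"  {'_'.join(map(str, name)):16s} "
          f"estimate {est:6.2f}  90% CI [{lo:6.2f}, {hi:6.2f}]  "
          f"(true {truth})")
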