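"""Fluctuating asymmetry from replicated antimere landmark data.

Simulates 40 individuals' upper first molars (both sides, 3 replicate
digitizations each), then runs the full shape workflow: reflect the right
antimeres, slide the 20 outline semilandmarks against the consensus
(bending-energy criterion), GPA-align everything, project to tangent space,
and decompose variation with a two-way mixed-model Procrustes ANOVA.

The ANOVA's interaction term (individual x side) is the fluctuating
asymmetry signal; the error row is intra-observer digitizing error. F(FA) =
MS(FA)/MS(error) says how far the asymmetry signal rises above measurement
noise, and the permutation p tells whether it is significant.
"""

import pandas as pd

from dentasym import LandmarkScheme, analyze_tooth_class, simulate_landmarks
from dentasym.synthetic_data import ShapeSimParams

scheme = LandmarkScheme.for_tooth("UM1")
params = ShapeSimParams(scheme=scheme, n_individuals=40, seed=7)
config_set, truth = simulate_landmarks(params)
print(f"simulated {len(config_set)} configurations "
      f"({params.n_individuals} individuals x 2 sides x {params.n_replicates} replicates)")

analysis = analyze_tooth_class(config_set, n_perm=499, seed=7)

pd.set_option("display.float_format", lambda v: f"{v:.4f}")
print("\nProcrustes ANOVA (tangent coordinates):")
print(analysis.anova.to_frame().to_string(index=False))
print(
    f"\nFA accounts for {100 * analysis.anova.r2['ind_x_side']:.1f}% of shape "
    f"variation and is {analysis.anova.f['ind_x_side']:.1f}x the digitizing error "
    f"(permutation p = {analysis.anova.p['ind_x_side']:.3f})."
)
print("\nfirst per-individual FA scores (DA-corrected antimere difference norms):")
print(analysis.scores.head().to_string(index=False))
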