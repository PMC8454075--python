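"""Detect genotype-dependent probe failure from bead-level noise statistics.

Probe failure acquires background-only fluorescence; the per-entry
noise-to-signal statistic CV_logT (built from the across-bead channel SDs
stored in the raw files) is high for failed entries.  When failure strikes
only one genotype class, the CV_logT distribution across samples turns
bimodal -- flagged when its bimodality coefficient exceeds 5/9 -- and, being
genetically determined, it agrees between monozygotic co-twins -- flagged
when the twin correlation exceeds 0.8.  Both criteria jointly define the
"ambivalent failure" call.
"""

import numpy as np

import umscan as um
from umscan.simulate import ProbePatternSpec

cohort, factors = um.simulate_cohort(um.CohortSpec(n_pairs=400, seed=3))
rng = np.random.default_rng(1)

probes = {
    "failing_snp_probe": ProbePatternSpec(pattern=um.Pattern.SNP_EQ_PF, maf=0.3),
    "healthy_probe": ProbePatternSpec(pattern=um.Pattern.CONSTANT_M),
    "y_probe": ProbePatternSpec(pattern=um.Pattern.Y_PROBE),
}
import pandas as pd

rows = [um.simulate_probe(ps, cohort, factors, rng, probe_id=name) for name, ps in probes.items()]
idx = pd.Index([r.probe_id for r in rows], name="probe_id")
cols = pd.Index(cohort.sample_ids, name="sample_id")
intens = um.IntensityMatrices(
    U=pd.DataFrame([r.u for r in rows], idx, cols),
    M=pd.DataFrame([r.m for r in rows], idx, cols),
    sigma_U=pd.DataFrame([r.sigma_u for r in rows], idx, cols),
    sigma_M=pd.DataFrame([r.sigma_m for r in rows], idx, cols),
)

stats = um.compute_noise_statistics(intens, cohort)
print(f"{'probe':20s} {'BC(CV_logT)':>12s} {'cor_MZ':>8s} {'flagged':>8s}")
for pid in intens.probe_ids:
    print(
        f"{pid:20s} {stats.bc[pid]:>12.3f} {stats.cor_mz[pid]:>8.3f} "
        f"{str(bool(stats.flags[pid])):>8s}"
    )
print(
    "\nBC > 5/9 (= 0.556, the uniform distribution's value) marks"
    "\nmultimodal noise; cor_MZ > 0.8 confirms it is genetically driven."
    "\nThe Y probe fails in every female, so its failure is sex-linked and"
    "\nequally heritable."
)
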