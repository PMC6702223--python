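"""Recover a planted shared connectivity pattern: simulate multi-paradigm
time series, build per-paradigm connectivity matrices, extract each
subject's shared cross-paradigm component and score a circuit mask."""

import numpy as np

from twinconn import (ParadigmSimSpec, RoiTimeSeries, TwinCohortSpec,
                      VarianceComponentsSpec, average_sessions, compute_cpc,
                      network_score, pearson_connectivity,
                      simulate_multiparadigm_timeseries,
                      simulate_twin_phenotypes, vectorize_edges)

cohort = simulate_twin_phenotypes(TwinCohortSpec(
    n_mz=10, n_dz=5, components=VarianceComponentsSpec(a2=0.52, e2=0.48),
    seed=5))
paradigms = [ParadigmSimSpec(paradigm_id=f"par{k}", n_timepoints=200,
                             n_sessions=2) for k in range(8)]
sim = simulate_multiparadigm_timeseries(cohort, paradigms, n_nodes=50,
                                        shared_pattern_seed=6)
mask = sim.circuit_mask(top_k=50)  # strongest positive circuit edges

recovery, scores = [], []
for sid in cohort["subject_id"]:
    edge_vectors = []
    for p in paradigms:
        mats = [pearson_connectivity(RoiTimeSeries(
            sid, p.paradigm_id, str(s), sim.series[(sid, p.paradigm_id, s)],
            p.tr_seconds)) for s in (1, 2)]
        edge_vectors.append(vectorize_edges(average_sessions(mats)))
    result = compute_cpc(edge_vectors)
    recovery.append(abs(np.corrcoef(result.loadings,
                                    sim.shared_pattern_edges)[0, 1]))
    scores.append(network_score(result, mask))

print(f"subjects: {len(cohort)}; paradigms: 8 x 2 sessions; 50 nodes")
print(f"mean |r| loadings vs planted shared pattern: {np.mean(recovery):.3f}")
print(f"network score vs latent phenotype r: "
      f"{np.corrcoef(scores, cohort['phenotype'])[0, 1]:.3f}")
# The first SVD component recovers the planted cross-paradigm pattern
# (|r| near 1), and the circuit-masked score tracks each subject's latent
# phenotype, so twin correlation structure survives the imaging pipeline.
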