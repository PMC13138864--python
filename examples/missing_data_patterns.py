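"""How the missing-data pattern changes the required cluster count.

Same marginal observation probabilities (40% dropout by the last of six
visits), three joint structures: independent misses (IM), monotone dropout
(MM), and a 50/50 mixture (MIX).  Monotone dropout concentrates the loss on
few subjects and always costs the most clusters.
"""

from crtlm import (
    ClusterSizeModel,
    CorrelationSpec,
    DesignSpec,
    MissingnessSpec,
    required_clusters,
)

design = DesignSpec(p=0.5, sigma2=1.0, beta4=0.04, times=tuple(range(6)))
corr = CorrelationSpec(structure="CS", rho1=0.30, rho2=0.05, rho3=0.025)
cluster = ClusterSizeModel.fixed(15)
delta = (1.00, 0.85, 0.70, 0.66, 0.63, 0.60)

complete = required_clusters(design, corr, cluster=cluster)
print(f"complete data: n = {complete.n}")
for pattern in ("IM", "MIX", "MM"):
    miss = MissingnessSpec(pattern=pattern, delta=delta, w=0.5)
    res = required_clusters(design, corr, miss, cluster)
    print(f"{pattern:>4} pattern:   n = {res.n}  (power {res.achieved_power:.4f})")

print()
print("Meaning: identical per-visit observation rates cost 24-29 extra")
print("clusters relative to complete data, and dropout (MM) costs more than")
print("intermittent misses (IM) because whole tails of trajectories vanish.")
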