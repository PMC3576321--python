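"""The full pipeline on a generated study with a known switch at t = 30.

Simulates a zero-noise bundle (model + medium + expression + DE table),
runs weighting -> dispensability partition -> per-time bilevel
extraction -> EFM enumeration -> profiles, and shows that the analysis
recovers the scheduled adaptation event.
"""

import tempfile
from pathlib import Path

from adam import RunConfig, run_adam
from adam.synthetic import SyntheticScenario, end_to_end_fixture

scenario = SyntheticScenario(seed=17, noise_sd=0.0)
tmp = Path(tempfile.mkdtemp())
paths = end_to_end_fixture(scenario, tmp / "bundle")
result = run_adam(
    RunConfig(
        model_path=paths["model"],
        medium_path=paths["medium"],
        expression_path=paths["expression"],
        differential_path=paths["differential"],
        out_dir=tmp / "out",
        seed=0,
    )
)

print("minimal networks per time point:")
for (cond, t), net in sorted(result.networks.items()):
    extras = sorted(net.included_set - set(result.partition.indispensable))
    print(f"  t={t:5.1f}: {net.n_reactions} reactions, dispensables kept: {extras}")
# The kept dispensable pair switches from path 0 to path 1 at t = 30, the
# scheduled activation time.

cond = result.by_condition["stress"]
print("\nconsecutive Jaccard (EFM sets | dispensable sets):")
for row in cond.transitions.consecutive.itertuples():
    print(f"  {row.time_from:5.1f} -> {row.time_to:5.1f}: "
          f"{row.jaccard_efm:.3f} | {row.jaccard_dispensable:.3f}")
# The unique minimum at 15 -> 30 localises the network transition.

print("\nprofile classes:")
print(cond.classification["class"].to_string())
print(f"\nstage outputs written to {tmp / 'out'}")
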