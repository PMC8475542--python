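"""Predict a ligand binding site by conservation-weighted pose rescoring.

Builds a small synthetic receptor with a conserved pocket, a set of docked
poses (one true pose among decoys), and ranks the poses by the product of
mean site conservation and docking energy. The most negative combined
score marks the predicted binding site.
"""

from condock import rank_poses
from condock.synthetic import ScenarioSpec, generate_scenario

scenario = generate_scenario(ScenarioSpec(seed=7, true_energy_percentile=0.7))
profile = scenario.profile()

ranked = rank_poses(scenario.receptor, scenario.poses, profile)

print(f"{'pose':>6} {'energy':>10} {'cons':>6} {'combined':>10} rank")
for r in ranked:
    print(f"{r.pose_id:>6} {r.energy_score:>10.1f} "
          f"{r.conservation_score:>6.3f} {r.condock_score:>10.1f} {r.rank:>4}")

top = ranked[0]
print(f"\npredicted site: pose {top.pose_id}, {top.site.n} residues, "
      f"mean conservation {top.conservation_score:.3f}")
print(f"planted true pose: {scenario.truth} "
      f"({'recovered' if top.pose_id == scenario.truth else 'missed'})")
# The true pose sits on conserved pocket residues (~0.89) while decoys touch
# weakly conserved surface (~0.22), so its product is by far the most
# negative even though several decoys have better raw docking energies.
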