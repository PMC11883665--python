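"""End-to-end placement: slice a model and fit the slices into a map.

Builds a 3-domain target map at 6 A from a planted ground truth, slices
the trimmed model into its 3 domains, adds a decoy slice that is absent
from the density, and runs the sequential placement loop: exhaustive
FFT fitting, classifier gating, fixed-model masking and clash
resolution.  Takes about a minute.
"""

import numpy as np

from slicefit import slice_by_coordinates, trim_by_confidence
from slicefit.classifier import balance_undersample, grouped_split, train
from slicefit.fitting import Placement, run_pipeline
from slicefit.slicer import Slice
from slicefit.structures import ca_coordinates
from slicefit.synthetic import (ClassifierFixtureSpec, PlantedModelSpec,
                                make_classifier_fixture, make_planted_model,
                                make_target_map)

model, _, _ = make_planted_model(PlantedModelSpec(
    n_domains=3, residues_per_domain=(60, 60, 60), seed=2))
trimmed, _ = trim_by_confidence(model)
dmap = make_target_map([(trimmed, Placement("t", np.eye(3), np.zeros(3),
                                            0.0))],
                       voxel=2.0, resolution=6.0)

assignment = slice_by_coordinates(trimmed, "birch", 3, seed=0)
order = {k: i for i, k in enumerate(trimmed.residue_keys())}
slices = [Slice(trimmed.model_id, i,
                sorted(assignment.members(i), key=order.__getitem__),
                trimmed.select(sorted(assignment.members(i),
                                      key=order.__getitem__),
                               model_id=f"dom{i}"))
          for i in range(1, 4)]
decoy, _, _ = make_planted_model(PlantedModelSpec(
    n_domains=1, residues_per_domain=(50,), seed=99))
slices.append(Slice("decoy", 4, decoy.residue_keys(), decoy))

clf_rows = make_classifier_fixture(ClassifierFixtureSpec(seed=1))
train_set, _ = grouped_split(balance_undersample(clf_rows, 1), 0.3, seed=1)
clf = train(train_set, seed=1)

result = run_pipeline(slices, dmap, clf, mode="sequential", seed=0,
                      angular_step=30.0)

print("accepted placements:")
for p in result.accepted:
    slc = next(s for s in slices
               if s.slice_id == p.slice_ref or s.model.model_id == p.slice_ref)
    truth = ca_coordinates(slc.model).coords
    got = ca_coordinates(result.placed_models[p.slice_ref]).coords
    rmsd = float(np.sqrt(((truth - got) ** 2).sum(axis=1).mean()))
    print(f"  {p.slice_ref}: probability {p.probability:.3f}, "
          f"local CC {p.score:.3f}, Calpha RMSD to truth {rmsd:.2f} A")
print("rejected placements:")
for p, why in result.rejected:
    print(f"  {p.slice_ref}: {why}")
print(f"combined local CC {result.combined_cc:.3f} "
      f"-> {result.assessment_band} at 6 A")
# The three real domains come back essentially at their true poses with
# probabilities near 1; the decoy, which has no density to explain, is
# rejected by the classifier gate.
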