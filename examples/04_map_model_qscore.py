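"""Map-model Q-score on a self-rendered density.

Renders a small rigid atom cluster as a Gaussian density map, scores
the model against its own map (near-perfect agreement), then shows how
the score degrades when the model is displaced or the map gets noisy.
"""

from dataclasses import replace

import numpy as np

from slc26kit.io import Atom, DensityMap, Structure
from slc26kit.qscore import q_score
from slc26kit.synthetic import render_density

ligand = Structure([
    Atom(serial=i + 1, name=f"C{i + 1}", element="C", residue_name="LIG",
         residue_seq=1, chain_id="L", position=np.asarray(p, float),
         vdw_radius=1.7, is_hetero=True)
    for i, p in enumerate([[0, 0, 0], [2.5, 0, 0], [0, 2.5, 0], [0.3, 0.4, 2.5]])
])

density = render_density(ligand, sigma=0.6, voxel=0.3)
print(f"self-rendered map Q-score: {q_score(density, ligand).selection_q:.3f} "
      "(1.0 = ideal agreement)")

shifted = Structure([replace(a, position=a.position + np.array([1.5, 0, 0]))
                     for a in ligand.atoms])
print(f"model displaced 1.5 A:    {q_score(density, shifted).selection_q:.3f}")

rng = np.random.default_rng(0)
noisy = DensityMap(values=density.values + 0.3 * float(density.values.max())
                   * rng.normal(size=density.values.shape).astype(np.float32),
                   voxel_size=density.voxel_size, origin=density.origin)
print(f"map with 30% noise:       {q_score(noisy, ligand).selection_q:.3f}")
# Experimental maps at 3-3.5 A resolution typically give Q ~ 0.6 for
# well-modeled atoms; a well-resolved ligand can score higher (e.g. 0.77).
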