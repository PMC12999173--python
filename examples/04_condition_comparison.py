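"""Detect a condition effect on hot-spot organisation, compartment by
compartment, with FDR control.

Two groups of simulated samples share everything except that the "treated"
group has its intensity-density coupling switched off in compartments g2
and g4 (as if a treatment transiently dissolved the hot spots there).  The
comparison should flag exactly those compartments.
"""

import numpy as np

from azprofile.core import CLUSTER_COLUMNS, ClusterTable
from azprofile.groups import condition_compartment_comparison
from azprofile.spatial import annotate_spatial, density_localintensity_correlation
from azprofile.synthetic import (
    apply_condition_effect,
    assign_marks,
    domain_for,
    hotspot_spec,
    sample_cluster_centers,
)
import pandas as pd


def sample_r(spec):
    """Per-compartment density/local-intensity R for one simulated sample."""
    domain = domain_for(spec)
    centers = sample_cluster_centers(spec, domain)
    marks = assign_marks(centers, spec, domain)
    df = pd.DataFrame({
        "id": np.arange(len(centers)),
        "x_um": centers[:, 0], "y_um": centers[:, 1], "z_um": centers[:, 2],
        "volume_vox": 1, "intensity": marks["intensity"].to_numpy(),
        "seed_z": -1, "seed_y": -1, "seed_x": -1,
        "compartment": marks["compartment"].to_numpy(),
    })[CLUSTER_COLUMNS]
    table = annotate_spatial(ClusterTable(df=df))
    _, per = density_localintensity_correlation(table, by_compartment=True)
    return per


control = [sample_r(hotspot_spec(seed=s)) for s in range(8)]
treated = [sample_r(apply_condition_effect(hotspot_spec(seed=100 + s),
                                           ["g2", "g4"], decoupling=1.0))
           for s in range(8)]

comps = ["g1", "g2", "g3", "g4", "g5"]
result = condition_compartment_comparison(control, treated, comps, q=0.05)
print(result.table.to_string(index=False,
                             float_format=lambda v: f"{v:.4f}"))
print(f"\nrejected at FDR 0.05: {result.rejected_compartments()}")
print("'diff' is mean R(control) - mean R(treated): positive where the "
      "treatment removed the density-intensity coupling")
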