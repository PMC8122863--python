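#!/usr/bin/env python
"""Pack the three nanoparticle clusters and characterize their composition.

Each cluster holds 333 gold nanoparticles (radius one tenth of the
bounding radius) placed at random without overlap.  This script packs
all three size classes, verifies the hard-sphere constraints with an
independent check, reports the effective gold-water mixture density
(the MixNP surrogate), and resolves the radial gold-fraction profile,
whose depleted outer shell is the geometric origin of the near-surface
dose differences between cluster and mixture.
"""

import numpy as np
import pandas as pd

from nanolem.clusters import (
    ClusterSpec,
    gold_volume_fraction,
    mixture_density,
    radial_gold_fraction,
    sample_cluster,
    two_shell_equivalent,
    validate_realization,
)
from nanolem.rdd import SIZE_CLASSES

OUT = "results"
SEED = 2021

rows = []
for size, r_np in SIZE_CLASSES.items():
    spec = ClusterSpec(n_np=333, r_np=r_np, r_bound=float(size))
    real = sample_cluster(spec, seed=SEED)
    validate_realization(real)
    prof = radial_gold_fraction(real, n_shells=10, n_samples=400_000, seed=SEED + 1)
    two = two_shell_equivalent(spec)
    rows.append(
        {
            "size_class_nm": size,
            "r_np_nm": r_np,
            "gold_volume_fraction": gold_volume_fraction(spec),
            "mixture_density_g_cm3": mixture_density(spec),
            "interior_gold_fraction_mc": prof.volume_weighted_mean(),
            "outer_shell_gold_fraction_mc": prof.fraction[-1],
            "two_shell_core_density_g_cm3": two.rho_inner,
        }
    )
    print(
        f"{size:>4} nm cluster: packed 333 NPs (non-overlap verified); "
        f"mixture density {mixture_density(spec):.2f} g/cm^3; "
        f"MC gold fraction {prof.volume_weighted_mean():.4f} "
        f"(outer shell {prof.fraction[-1]:.3f} -- depleted vs nominal 0.333)"
    )

df = pd.DataFrame(rows)
df.to_csv(f"{OUT}/cluster_packing_summary.csv", index=False)
print(f"\nAll three classes share the nominal gold fraction 0.333, hence the")
print(f"same 7.1 g/cm^3 homogeneous-mixture density; concentrating the gold")
print(f"in a water-jacketed core (two-shell variant) raises the core density")
print(f"to {rows[0]['two_shell_core_density_g_cm3']:.2f} g/cm^3.")
print(f"Wrote {OUT}/cluster_packing_summary.csv")
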