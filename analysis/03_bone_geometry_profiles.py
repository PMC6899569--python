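#!/usr/bin/env python
"""Cross-sectional geometry profiles along synthetic tibiae, with the
per-position genotype significance heat map.

Simulates two genotype groups x two sexes of tibia-like stacks (tapered,
rotated elliptical annuli with specimen-to-specimen jitter; the "KO female"
group carries a genuine reduction in cortical thickness and cross-section),
profiles CSA, I_min, I_max, J, Ct.Th, ellipticity and calibrated BMD at
10-90%% of bone length, runs a sex x genotype ANOVA per position and
endpoint, and bins the genotype-effect p-values into the significance
heat-map colours.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from dimorphbone import (DensityCalibration, cross_section_profile,
                         significance_heatmap, two_way_anova)
from dimorphbone.phantom import TibiaPhantomSpec, generate_tibia_stack
from dimorphbone.volumes import BinaryMask

ENDPOINTS = ["csa_um2", "i_min_um4", "i_max_um4", "j_um4", "ellipticity",
             "ct_th_um", "bmd_mg_ha_cm3"]


def simulate_specimen(rng, genotype: str, sex: str) -> pd.DataFrame:
    shrink = 0.82 if (genotype == "KO" and sex == "F") else 1.0
    outer = rng.normal(110.0, 4.0)
    wall = rng.normal(45.0, 2.0) * shrink
    spec = TibiaPhantomSpec(
        n_slices=40, pixel_size_um=2.0, image_size=192,
        outer_a_um=(outer * 1.15, outer * 0.9),
        outer_b_um=(outer * 0.95, outer * 0.8),
        inner_a_um=(outer * 1.15 - wall, outer * 0.9 - wall),
        inner_b_um=(outer * 0.95 - wall, outer * 0.8 - wall),
        rotation_deg=(0.0, 25.0),
        bone_intensity=int(np.clip(rng.normal(200 * shrink ** 0.5, 4), 0, 255)),
    )
    volume, _ = generate_tibia_stack(spec)
    bone = BinaryMask(volume.voxels >= 100, spec.pixel_size_um)
    calibration = DensityCalibration.from_phantom([50.0, 200.0], [250.0, 1000.0])
    profile = cross_section_profile(bone, intensities=volume,
                                    calibration=calibration)
    profile["genotype"] = genotype
    profile["sex"] = sex
    return profile


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--n-per-group", type=int, default=4)
    parser.add_argument("--out", type=Path, default=Path("results"))
    args = parser.parse_args()
    rng = np.random.default_rng(args.seed)

    profiles = []
    for genotype in ("WT", "KO"):
        for sex in ("F", "M"):
            for i in range(args.n_per_group):
                prof = simulate_specimen(rng, genotype, sex)
                prof["specimen"] = f"{genotype}_{sex}_{i + 1}"
                profiles.append(prof)
    table = pd.concat(profiles, ignore_index=True)
    args.out.mkdir(parents=True, exist_ok=True)
    table.to_csv(args.out / "geometry_profiles.csv", index=False)

    pvals = {}
    for endpoint in ENDPOINTS:
        by_pos = {}
        for pos, group in table.groupby("position_pct"):
            res = two_way_anova(group[endpoint], group.sex, group.genotype)
            by_pos[pos] = res["genotype"].p_value
        pvals[endpoint] = by_pos
    p_table = pd.DataFrame(pvals)
    heatmap = significance_heatmap(p_table)
    p_table.to_csv(args.out / "geometry_pvalues.csv")
    heatmap.to_csv(args.out / "geometry_heatmap.csv")

    n_sig = int((p_table < 0.05).sum().sum())
    print(table.groupby(["genotype", "sex"]).ct_th_um.mean().round(1))
    print(f"\n{n_sig} of {p_table.size} position x endpoint genotype tests "
          f"significant at p<0.05 (injected effect: KO females only)")
    print(f"wrote {args.out / 'geometry_profiles.csv'}, p-values and heat map")


if __name__ == "__main__":
    main()
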