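#!/usr/bin/env python
"""Generate one synthetic field season per spring.

Writes every input type the pipeline consumes — Fe accretion and DNA
series, an O2 microprofile, SEM count fields, a community table and an
oxalate/ICP extraction table — for both springs, with the default noise
models, under results/synthetic/.
"""

from pathlib import Path

import numpy as np

from ferromat import io
from ferromat.config import NoiseSpec, site_config
from ferromat.synthetic import (
    gen_accretion_series,
    gen_community_table,
    gen_count_fields,
    gen_dna_series,
    gen_extraction_table,
    gen_microprofile,
)

OUT = Path(__file__).resolve().parents[1] / "results" / "synthetic"
SEED = 20160101

slide_times = np.arange(0.0, 71.0, 7.0)
sem_times = [4.0, 7.0, 10.0, 14.0]
community_times = [4.0, 10.0, 15.0, 30.0, 40.0, 55.0, 70.0]
extraction_times = np.arange(14.0, 71.0, 7.0)


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    for i, site in enumerate(("osp", "beowulf")):
        cfg = site_config(site)
        seed = SEED + i
        io.write_series(
            gen_accretion_series(cfg, slide_times, NoiseSpec("lognormal", 0.2, seed)),
            OUT / f"{site}_fe_series.csv")
        io.write_series(
            gen_dna_series(cfg, slide_times, NoiseSpec("lognormal", 0.2, seed + 10)),
            OUT / f"{site}_dna_series.csv")
        model = cfg.reaction_diffusion_model()
        z = np.arange(0.0, model.L_f * 1e4, 10.0)
        io.write_profile(
            gen_microprofile(model, z, NoiseSpec("gaussian", 0.02, seed + 20)),
            OUT / f"{site}_o2_profile.csv")
        counts = gen_count_fields(cfg.coloniz_rate_rod, sem_times, morphotype="rod",
                                  noise=NoiseSpec("poisson", 0.0, seed + 30))
        counts += gen_count_fields(cfg.coloniz_rate_coccus, sem_times,
                                   morphotype="coccus",
                                   noise=NoiseSpec("poisson", 0.0, seed + 31))
        io.write_counts(counts, OUT / f"{site}_sem_counts.csv")
        io.write_abundance(
            gen_community_table(cfg, community_times, NoiseSpec("dirichlet", 200, seed + 40)),
            OUT / f"{site}_community.tsv")
        io.write_icp(
            gen_extraction_table(cfg, extraction_times, NoiseSpec("lognormal", 0.2, seed + 50)),
            OUT / f"{site}_icp.csv")
        print(f"{site}: wrote 6 synthetic input files")
    print(f"done -> {OUT}")


if __name__ == "__main__":
    main()
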