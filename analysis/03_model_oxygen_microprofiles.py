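#!/usr/bin/env python
"""Reaction-diffusion analysis of the simulated O2 microprofiles.

For each spring: Fick's-law surface flux from the near-interface
gradient, fitted Thiele modulus (first-order slab solution), O2
penetration depth, and the diffusion-vs-reaction limitation verdict.
Also summarises the multi-year published flux survey (mean +/- SD).
"""

import json
from pathlib import Path

from ferromat import io, oxygen
from ferromat.config import site_config
from ferromat.datasets import o2_flux_survey

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    summary = {}
    for site in ("osp", "beowulf"):
        cfg = site_config(site)
        k1, d_e, l_f = cfg.profile_params
        profile = io.read_profile(ROOT / "synthetic" / f"{site}_o2_profile.csv")
        flux = oxygen.estimate_flux(profile, D_e=d_e)
        k1_hat, phi, rmse = oxygen.fit_profile(profile, "first", L_f=l_f, D_e=d_e)
        pen = oxygen.penetration_depth(profile)
        verdict = oxygen.classify_limitation(phi)
        summary[site] = {
            "flux_umol_cm2_s": flux.J, "thiele_modulus": phi,
            "k1_per_s": k1_hat, "rmse_u": rmse,
            "penetration_um": pen, "limitation": verdict,
        }
        print(f"{site}: J_O2 = {flux.J:.3g} umol/cm^2/s, phi = {phi:.1f} "
              f"({verdict}), O2 penetration = {pen:.0f} um")

    survey = o2_flux_survey()["flux_umol_cm2_s"]
    summary["flux_survey"] = {
        "mean": survey.mean(), "sd": survey.std(ddof=1), "n": int(survey.size),
    }
    print(f"published survey: mean flux = {survey.mean():.2g} "
          f"+/- {survey.std(ddof=1):.1g} umol/cm^2/s (n={survey.size})")
    ROOT.mkdir(exist_ok=True)
    io.write_json_report(summary, ROOT / "oxygen_summary.json")
    print(f"wrote {ROOT / 'oxygen_summary.json'}")


if __name__ == "__main__":
    main()
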