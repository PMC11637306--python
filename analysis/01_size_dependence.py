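"""Homogeneous-conductance AP propagation along a synthetic varicose axon.

Simulates a single AP with uniform Na/K densities (g_na 290, g_k 17
mS/cm^2) and the GHK Ca channel mixture on the seeded synthetic mossy-fiber
axon, measures AP shape at every micrometer, and summarizes how the
repolarization area and the downstream release efficacy vary with local
size.  Writes per-compartment and per-bouton tables under results/.
"""

import sys

from axonwave.experiments import report_summary, run_experiment


def main(seed: int = 1, outdir: str = "results/size_dependence") -> None:
    report = run_experiment("size_dependence", seed=seed)
    report.save(outdir)
    print(report_summary(report))
    s = report.summary
    reg = s["repol_area_vs_capacitance"]
    print()
    print(f"Finding: with homogeneous conductances the per-compartment "
          f"repolarization area varies (sd {s['repol_area_sd']:.2f} mV*ms) "
          f"and its regression on local capacitance has slope "
          f"{reg['slope']:.1f} mV*ms/pF (r = {reg['r']:.3f}).")
    print(f"Across boutons, relative release spreads by "
          f"{100 * s['release']['rel_range']:.0f}% of the mean "
          f"(cv {100 * s['release']['cv']:.0f}%).")
    print(f"Tables written to {outdir}/")


if __name__ == "__main__":
    main(seed=int(sys.argv[1]) if len(sys.argv) > 1 else 1)
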