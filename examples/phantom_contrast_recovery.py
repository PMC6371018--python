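"""Phantom contrast recovery: pick the RL stopping iteration from Q_H/RMSE.

Simulates the digital eight-sphere Jaszczak phantom (13:1 hot-sphere
contrast), degrades it with a 12 mm FWHM Gaussian PSF and Poisson noise,
runs Richardson-Lucy deconvolution and reports the contrast recovery
coefficient Q_H per sphere before and after recovery.
"""

from y90quant.pipeline import RunConfig, run_phantom_qc

report = run_phantom_qc(RunConfig(seed=0, phantom_shape=(64, 64, 48)))

print(f"selected RL iteration: {report['selected_iteration']} "
      f"(max Q_H among RMSE-declining iterations, 34 mm sphere)")
print(f"calibration factor from phantom counts: "
      f"{report['cf_estimate_cps_per_MBq']:.0f} cps/MBq "
      f"(forward model used {report['cf_forward_model_cps_per_MBq']:.0f})")
print(f"{'sphere':>12} {'Q_H before':>11} {'Q_H after':>10} {'activity err %':>15}")
for name, s in report["spheres"].items():
    err = "n/a" if s["percent_error"] is None else f"{s['percent_error']:8.1f}"
    print(f"{name:>12} {s['qh_initial_pct']:10.1f}% {s['qh_recovered_pct']:9.1f}% {err:>15}")

print("\nQ_H = 100% would mean the full 13:1 contrast survived imaging; "
      "recovery helps the larger spheres most, while the smallest inserts "
      "stay partial-volume and noise dominated.")
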