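"""Run the dual-GLH pipeline on a two-volume phantom and read the report.

The first gray-level-histogram pass thresholds SPECT uptake inside the user
ROI (V_SPECT, inflated by radiation spillover); the second applies an
adaptive HU band to the CT voxels inside that mask (V_SPECT-CT, spillover
free).  Their ratio R > 1 quantifies how much spillover the CT pass removed.
"""

from remnantvol import PhantomSpec, SphereSpec, generate_pair, run_pipeline

spec = PhantomSpec(
    spheres=[
        SphereSpec((66.0, 87.45, 33.0), 1.5, activity_conc=0.493),
        SphereSpec((92.3, 87.45, 33.0), 3.0, activity_conc=0.432),
    ],
    ct_shape=(160, 160, 16),
    neck_radius_mm=62.0,
    isotope="I-131",
    seed=3,
)
pair, truth = generate_pair(spec)
report = run_pipeline(
    pair.spect, pair.ct, truth.roi_combined, truth=truth.truth_records()
)

print(f"SPECT threshold: {report.spect_threshold.threshold:.1f} counts")
print(f"adaptive HU band: [{report.hu_band.lo:.0f}, {report.hu_band.hi:.0f}]")
print(f"{'true (mL)':>10} {'V_SPECT':>8} {'V_SPECT-CT':>11} {'R':>6} {'%dV':>6}")
for vol in sorted(report.volumes, key=lambda v: v.true_volume_ml):
    print(
        f"{vol.true_volume_ml:>10.1f} {vol.v_spect:>8.3f} "
        f"{vol.v_spect_ct:>11.3f} {vol.ratio_r:>6.2f} {vol.pct_delta_v:>6.1f}"
    )
# V_SPECT overshoots the true volumes severalfold (spillover + the coarse
# SPECT lattice); V_SPECT-CT lands within a few percent of 1.5 and 3 mL.
# At 1 cm separation under I-131-like blur the two SPECT masks merge into
# one component (spect_component_shared=True), so each volume reports the
# shared V_SPECT; the CT masks stay separate, which is what identifies the
# two volumes.
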