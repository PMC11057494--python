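"""Simulate a pulsating left ventricle and measure its ejection fraction.

Builds a three-cycle synthetic A4C sequence with a known 55% EF,
rasterises the LV masks, and runs the full measurement chain (area
curve -> ED/ES detection -> Jeffrey refinement -> area-length volumes
-> all-cycle EF).  The printed error shows how closely the pixel-level
pipeline recovers the analytic truth.
"""

from echolvef import LVShapeSpec, RhythmSpec, run_pipeline, simulate

rhythm = RhythmSpec(n_cycles=3, mean_period=40, seed=1)
shape = LVShapeSpec(long_axis_ed=80, short_axis_ed=40, per_cycle_ef=(55.0, 55.0, 55.0))
echo = simulate(rhythm, shape)

result, viz = run_pipeline(echo.masks)

print(f"truth EF        : {echo.truth.overall_ef:.2f}%")
print(f"pipeline EF     : {result.mean_ef:.2f}%  ({result.phenotype})")
print(f"absolute error  : {abs(result.mean_ef - echo.truth.overall_ef):.2f} EF points")
print(f"cycles detected : {result.n_cycles} at ED frames {list(viz.ed_markers)}")
for c in result.cycles:
    print(f"  cycle {c.cycle_index}: ED frame {c.ed_frame}, ES frame {c.es_frame}, "
          f"EF {c.ef:.2f}%")
# The per-cycle EFs agree because the rhythm is regular; the all-cycle
# mean is what the method reports for the video.
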