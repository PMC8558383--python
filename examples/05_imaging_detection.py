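"""Time-of-flight imaging: find two implanted insects in a leaf bed.

Simulates a 96 x 96 x 512 reflection cube (0.2 mm raster step) with
two elliptical inclusions, maps per-pixel peak amplitude and arrival
time, windows the grayscale to the attenuated range and runs the
shape-gated detector.
"""

from thzfb import PipelineConfig, run_imaging
from thzfb.imaging import component_iou

result = run_imaging(PipelineConfig(seed=0))

print(f"grayscale range:      {result.grayscale.value_range[0]:.3f} - "
      f"{result.grayscale.value_range[1]:.3f} a.u.")
print(f"delay contrast:       {result.delay_contrast_ps:.3f} ps "
      "(programmed insect delay: 0.800 ps)")
print(f"accepted detections:  {len(result.detection.accepted)}")
for comp, iou in zip(result.detection.accepted,
                     component_iou(result.detection, result.true_mask)):
    print(f"  component at ({comp.centroid[0]:5.1f}, {comp.centroid[1]:5.1f}) px, "
          f"area {comp.area_px} px, eccentricity {comp.eccentricity:.2f}, "
          f"IoU vs truth {iou:.2f}")
print()
print("Both inclusions are recovered with high overlap; the delay map")
print("confirms the longer flight time over insect material.")
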