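"""Chan-Vese tumor segmentation and the tumor-to-liver ratio (TLR).

Simulates a liver with a single tumor of true uptake ratio 5, degrades it
with blur and Poisson noise, contrast-recovers the image, segments the
high-uptake phase inside the liver VOI and compares the measured TLR with
the ground truth.
"""

from y90quant.recover import PsfModel, contrast_recover
from y90quant.segment import chan_vese, tlr
from y90quant.synthdata import AcquisitionModel, LiverStudySpec, make_paired_study

spec = LiverStudySpec(shape=(64, 64, 48))  # default tumor: uptake x5
model = AcquisitionModel(noise="poisson", seed=11)
pair = make_paired_study(spec, model, model)
y90 = pair["study_b"]

rec = contrast_recover(y90.spect, PsfModel(12.0), max_iterations=6)
seg = chan_vese(rec.final, y90.ct_masks["whole_liver"])
measured = tlr(rec.final, seg.tumor, seg.healthy)
raw = tlr(y90.spect, seg.tumor, seg.healthy)

print(f"true TLR (activity ground truth): {pair['truth']['true_tlr']:.2f}")
print(f"TLR on raw blurred image:         {raw:.2f}")
print(f"TLR after contrast recovery:      {measured:.2f}")
print(f"segmented tumor volume:           {seg.tumor_volume_ml:.0f} ml "
      f"(converged={seg.converged}, {seg.iterations_used} iterations)")

print("\nBlur smears tumor counts into the healthy liver and biases TLR low; "
      "Richardson-Lucy recovery restores most of the lost contrast before "
      "the ratio of mask means is taken.")
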