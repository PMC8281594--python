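"""Generate synthetic sinus and AF rhythms and inspect their R-R structure.

Builds one normal-sinus and one AF record at 250 Hz, detects R-peaks,
and prints the R-R coefficient of variation (CV) of each: sinus rhythm
stays well below the 0.15 irregularity threshold, AF well above it,
and the AF record has no P-waves (a fibrillatory baseline instead).
"""

from afibnet import RhythmParams, SynthConfig, detect_r_peaks, generate_record

sinus = generate_record(SynthConfig(
    fs=250, duration=30.0, rhythm=RhythmParams.normal_sinus(mean_hr=75), seed=1))
af = generate_record(SynthConfig(
    fs=250, duration=30.0, rhythm=RhythmParams.atrial_fibrillation(mean_hr=95), seed=1))

for name, rec in [("sinus", sinus), ("AF", af)]:
    peaks = detect_r_peaks(rec)
    print(f"{name:>5}: {len(rec)} samples, {len(peaks)} beats, "
          f"R-R CV = {peaks.rr_cv:.3f}")

print("\nThe R-R CV separates the rhythms at the 0.15 threshold: "
      "near-constant intervals for sinus, 'irregularly irregular' for AF.")
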