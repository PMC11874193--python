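"""Extract single-trial N100 peaks from a cleaned synthetic recording.

Runs the preprocessing chain (band-pass, channel rejection, artifact
suppression, 40 Hz low-pass + 250 Hz downsampling, sequence
segmentation), then the ERP steps: 20 Hz low-pass on [-1, 8] s epochs,
global mean correction, and peak search in the 60 ms window centred
100 ms after each standard tone at positions 3-7.
"""

from isochron import (ParadigmSpec, SubjectParams, erp_segment, global_center,
                      n100_peaks, peak_variability, preprocess_recording,
                      synth_subject)

spec = ParadigmSpec(n_sequences=24)
params = SubjectParams(group="young", evoked_amp=-4.0, latency_jitter_sd=0.008)
rec, events = synth_subject(spec, params, seed=2)

epochs, report = preprocess_recording(rec, events)
print(f"cleaning: {len(report.bad_channels)} bad channels, "
      f"{sum(len(v) for v in report.interpolated_windows.values())} "
      "interpolated artifact spans")

erp = global_center(erp_segment(epochs))
peaks = n100_peaks(erp, events, subject_id="demo")
print(f"{len(peaks)} single-trial peaks (24 sequences x positions 3-7)")
print(f"mean amplitude {peaks['amplitude'].mean():.2f} "
      f"(injected kernel depth {params.evoked_amp}; the global-mean "
      "correction and filters shift/attenuate it slightly)")
print(f"mean latency {peaks['latency'].mean() * 1000:.1f} ms "
      f"(injected 100 ms with {params.latency_jitter_sd * 1000:.0f} ms jitter)")

var = peak_variability(peaks)
print(f"intra-individual variability: var(amplitude) = "
      f"{var.loc[0, 'var_amplitude']:.3f}, var(latency) = "
      f"{var.loc[0, 'var_latency'] * 1e6:.0f} ms^2x10^-6 "
      f"(injected jitter contributes {params.latency_jitter_sd**2 * 1e6:.0f}; "
      "background noise moving the single-trial extremum adds the rest)")
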