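"""Identify a spiked-extract spectrum against the fingerprint library.

Simulates a QuEChERS-style extract on a silicon wafer (strong Si band at
521 cm^-1 plus a broad 900-1000 cm^-1 band on top of the analyte
fingerprint), preprocesses it, matches its prominent peaks against the
packaged library, and converts the spike concentration to ppm.
"""

from ramanid import SyntheticConfig, match_to_library, ppm_from_micromolar, top_k_peaks
from ramanid.library import get_record, load_library
from ramanid.preprocess import preprocess_spectrum
from ramanid.synth import simulate_spectrum

record = get_record("Chlormequat chloride")
cfg = SyntheticConfig(seed=3, spiked_extract_mode=True)
extract = simulate_spectrum(record, cfg, replicate=0)
processed, _ = preprocess_spectrum(extract)

peaks = top_k_peaks(processed, k=8)
print("prominent peaks of the spiked extract (cm^-1):",
      [round(p.position) for p in peaks])
# 521 cm^-1 is the Si wafer, not the analyte; the remaining peaks carry
# the pesticide fingerprint.
analyte_peaks = [p for p in peaks if abs(p.position - 521) > 5]

ranked = match_to_library(analyte_peaks, load_library(), tol=5.0)
print("\nbest library matches (score = weighted matched-peak fraction):")
for rec, score in ranked[:3]:
    print(f"  {score:.3f}  {rec.name}")

mass = record.molar_mass
print(f"\n{record.name}: M = {mass:.2f} g/mol "
      f"(from formula {record.molecular_formula})")
print(f"a 10 uM spike corresponds to {ppm_from_micromolar(10.0, mass):.2f} ppm")
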