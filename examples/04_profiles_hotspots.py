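"""From raw scan output to normalized profiles and hotspot statistics.

Normalizes mean ΔREU values to the 0–100 scale, smooths with a
5-residue window, partitions residues into hotspots (>40) and neutral
(<10), computes a Kyte–Doolittle hydropathy track for a tau fragment,
and compares hotspot vs neutral groups with an exact Mann–Whitney test.
"""

from fibrilscan import (
    CrossBetaPotential,
    ScanConfig,
    generate_fibril,
    hydropathy_profile,
    identify_hotspots,
    mann_whitney_exact,
    normalize_profile,
    run_alanine_scan,
    window_average,
)
from fibrilscan.synthetic import planted_hotspot_spec

spec, planted = planted_hotspot_spec(n_layers=9)
scan = run_alanine_scan(generate_fibril(spec),
                        ScanConfig(n_replicates=1, include_interface=False,
                                   rng_seed=0),
                        CrossBetaPotential())

profile = normalize_profile(scan.profile_with_na(), structure_id="demo")
profile.window = window_average(profile, 5)
hs = identify_hotspots(profile)
print(f"hotspots (normalized ΔREU > 40): {sorted(hs['top'])}")
print(f"neutral  (normalized ΔREU < 10): {sorted(hs['bottom'])}")

raw = profile.raw_mean
test = mann_whitney_exact([raw[p] for p in hs["top"]],
                          [raw[p] for p in hs["bottom"]])
print(f"hotspot vs neutral: U = {test.u_statistic:.1f}, "
      f"two-sided p = {test.p_two_sided:.4g} ({test.method})")

track = hydropathy_profile("VQIVYKPVDLSKVTSKC", w=5)
print("VQIVYK… hydropathy (5-residue window):",
      [round(v, 2) for v in track.windowed[:6]])
# The planted hotspots separate cleanly from the serine background; the
# amyloid motif's N-terminal window is strongly hydrophobic.
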