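"""LC-MS/MS run summarization and spectrum-format round trips.

Simulates a small data-dependent acquisition run (10 MS1 scans, each
triggering 4 MS2 scans), writes it to FT2 and MGF, reads it back, and
prints the run summary: per-level scan counts, TIC totals, and the MS2
precursor map size.
"""

import tempfile
from pathlib import Path

from sipsim import summarize_run
from sipsim.spectra_io import read_ft2, read_mgf, write_ft2, write_mgf
from sipsim.synthetic import make_run

run = make_run(n_ms1=10, n_ms2_per_ms1=4, gradient_minutes=5.0, seed=3)
print(f"simulated run: {len(run)} scans over 5 minutes")

with tempfile.TemporaryDirectory() as tmp:
    ft2 = Path(tmp) / "run.ft2"
    mgf = Path(tmp) / "run.mgf"
    write_ft2(run, ft2)
    write_mgf([s for s in run if s.ms_level == 2], mgf)
    back = read_ft2(ft2)
    print(f"FT2 round trip: wrote {len(run)} scans, read {len(back)} back")
    print(f"MGF round trip: {len(read_mgf(mgf))} MS2 scans")

summary = summarize_run(run, time_bin=1.0)
for level in (1, 2):
    rt, tic = summary.tic[level]
    counts = summary.scan_rate[level][1]
    print(f"MS{level}: {rt.size} scans, total TIC {tic.sum():.3g}, "
          f"scan rate per minute {counts.tolist()}")
print(f"precursor map: {summary.precursor_map[0].size} MS2 precursors")

# The scan-rate trace and precursor map are the summaries one inspects
# first on a real run to judge acquisition health before any searching.
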