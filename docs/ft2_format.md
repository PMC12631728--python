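# The FT2 centroided-spectrum dialect

FT2 is a plain-text, tab-separated format for centroided spectra emitted by
the Raxport raw-file converter.  No formal standard exists, so this package
pins the dialect it reads and writes here.  `sipsim.spectra_io.read_ft2`
accepts this grammar; `write_ft2` emits it.

## Grammar

One file holds any number of scan blocks.  Lines are tab-separated; the
first field is a tag:

| Tag | Fields | Meaning |
|-----|--------|---------|
| `H` | free text | file-level header, ignored on read |
| `S` | scan number, scan number, [precursor m/z] | starts a scan block; a precursor m/z marks an MS2 scan |
| `I` | key, value | scan metadata; `RetentionTime` (minutes), `MSLevel`, and `IsolationWidth` (Da) are interpreted, any other key is preserved verbatim in `Spectrum.extra` |
| `Z` | charge, neutral mass | precursor charge state and neutral (uncharged) mass |
| *(none)* | m/z, intensity, [resolution, baseline, noise, charge] | one centroided peak; only the first two columns are required |

Peaks belong to the most recent `S` block.  A malformed `S`, `Z`, or peak
line is a parse error that names the line number.  An empty file is an
empty scan list.

## Worked example

```
H	Extractor	sipsim
S	1	1
I	RetentionTime	0.50
I	MSLevel	1
400.2	150000
401.2	38000
S	2	2	400.2
I	RetentionTime	0.52
I	MSLevel	2
I	IsolationWidth	5
Z	2	798.385448
200.1	1200	30000	10	5	1
300.2	900
```

Scan 1 is an MS1 scan at 0.50 min with two peaks.  Scan 2 is a
data-dependent MS2 scan on precursor m/z 400.2 (charge 2, neutral mass
798.385448 Da) with a 5 Da isolation window; its first peak carries the
optional resolution/baseline/noise/charge columns.
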