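# spiroqc

Automatic quality assessment of forced-spirometry (FS) maneuvers from curve
morphology.

Forced spirometry measures expired volume and flow during a maximal
exhalation; the indices clinicians rely on (FVC, FEV₁, PEF) are only valid if
the maneuver itself was performed well — a decisive start, a single sharp
peak, a smooth descent and a genuine end-of-test plateau. Judging this
normally requires an experienced technician looking at the volume-time (VT),
flow-time (FT) and flow-volume (FV) curves. `spiroqc` automates that
judgment so testing can move to primary-care settings: it computes the
classical indices, segments each curve into five morphology zones, evaluates
a battery of shape criteria alongside the traditional ATS/ERS acceptability
rules, and grades every maneuver

* **0** — reject (bad morphology),
* **1** — acceptable, or
* **2** — refer to an expert.

## The indices and rules at the core

With the back-extrapolated time origin T₀ (the zero-volume crossing of the
steepest tangent to the VT curve):

* **BEV** = V(T₀), the back-extrapolated volume; a hesitant start is flagged
  when BEV > max(0.15 L, 5% FVC).
* **EOTV** = max − min volume over the final 1 s; a missing end-of-test
  plateau is flagged when EOTV ≥ 0.025 L.
* **FET100** = time from T₀ until the VT curve reaches FVC; exhalations
  shorter than 6 s (adults) are flagged.
* **Repeatability** — a session passes when it holds ≥ 3 acceptable
  maneuvers, two of which agree on both FVC and FEV₁ to within 0.15 L.

Around these, zone-wise shape criteria (C1–C12) detect irregular ascent,
late/flat/bimodal/slow peaks, irregular descent, end-of-test oscillation and
cough transients from first/second derivatives of the FV and FT curves. A
configurable policy maps criterion failures to the three grades. Every
threshold lives in a flat YAML configuration (`spiroqc --print-default-config`).

A synthetic-maneuver generator (quarter-sine rise, exponential descent whose
decay constant is solved so the expired volume meets the requested FVC) plus
nine labeled defect transforms make the entire battery testable without
patient data; see `docs/methods.md`.

## Worked example

```python
from spiroqc import CleanParams, DefectSpec, assess_maneuver, generate_clean, inject_defect

clean = generate_clean(CleanParams(fvc=4.0, pef=8.0, rise_time=0.1, duration=8.0))
report = assess_maneuver(clean)
print(report.grade, {k: round(v, 3) for k, v in report.indices.to_dict().items()})

late = inject_defect(clean, DefectSpec(kind="delayed_start", severity=1.0))
bad = assess_maneuver(late)
print(bad.grade, bad.failed_ids, round(bad.indices.bev, 3))
```

prints

```
1 {'FVC': 3.999, 'FEV1': 3.511, 'PEF': 8.0, 'PEFT': 0.064, 'T_zero': 0.036, 'BEV': 0.08, 'EOTV': 0.0, 'Tex': 3.174, 'FET100': 7.964}
0 ['C1', 'C2a', 'C2b', 'C8', 'C12a'] 0.5
```

The clean maneuver recovers its generating parameters (FVC 4 L, PEF 8 L/s)
and is graded acceptable. The delayed-start variant expires 0.5 L before the
main blast, so its back-extrapolated volume (0.5 L) exceeds the
max(0.15 L, 5% FVC) = 0.2 L limit: the BEV criterion C8 fails (and the
hesitant two-phase rise additionally trips the ascent-shape and
secondary-peak criteria) and the maneuver is rejected.

The same pipeline is available from the shell:

```bash
spiroqc simulate --out-dir ds --n-clean 100 --n-per-defect 20 --seed 1
spiroqc assess ds/curve_0000.csv
spiroqc evaluate ds/manifest.csv
```

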