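# lungnet

Complex-network texture analysis of lung HRCT crops, for quantifying diffuse
interstitial lung disease (DILD).

Radiological DILD assessment is pattern-based and subjective; this package
implements an objective alternative: translate a small HRCT sample into
pixel-adjacency networks, one per pathological attenuation band, and read
the texture off their degree distributions.

## Method

A 65×65-pixel crop (sized to contain one secondary pulmonary lobule at
~0.74 mm/px spacing, since a 25 mm lobule needs 25/0.74 ≈ 33.8 px) is taken
from a CT slice and converted to Hounsfield units via the DICOM rescale
`HU = slope · raw + intercept`. Each pixel is classified into half-open HU
bands; three are analysed:

| band | HU interval |
|---|---|
| emphysema | [−1024, −977) |
| ground-glass opacity (GGO) | [−703, −368) |
| consolidation | [−100, 5) |

Each band becomes an undirected graph *N(P, E)*: every in-band pixel is a
node with value *G(P)* (its HU), and

```
E = { {Px, Py} : d(Px, Py) ≤ Rd  and  |G(Px) − G(Py)| ≤ D }
```

with Euclidean pixel distance *Rd* = 4 (2.96 mm at 0.74 mm/px) and gradient
tolerance *D* = 50. The degree histogram of each network is then fitted with
three curve families — logarithmic `a·ln k + b`, power `a·k^b`, and
polynomial (degree chosen in [2, 8] by adjusted R²) — and summarised by
three metrics: total count (degree sum), average count (mean degree), and
maximum degree. Normal parenchyma yields sparse networks whose degree
histograms follow the logarithmic curve and reject the power curve;
clustered pathological texture yields humped histograms best fitted by a
polynomial, and much larger size metrics. Cohorts are compared with Welch's
two-sample t-test (unequal variances, Welch–Satterthwaite df) and a
standard-deviation share per group.

Patient data cannot ship with the package, so a synthetic phantom generator
produces normal-like and DILD-like crops with controlled HU-band occupancy
and clustering; every stage is testable against it.

## Worked example

```
python examples/03_cohort_statistics.py
```

```
total_count (combined pathological bands), DILD vs normal:
  mean DILD = 20902.7, mean normal = 347.6
  t = 14.85, df = 29, p(two-tail) = 4.3e-15
  t critical (two-tail, alpha=0.05) = 2.0452
  SD: DILD = 7578.9 (98.7%), normal = 97.7 (1.3%)
```

A 30+30 phantom cohort is generated, each crop is split into the three
bands, graphed, and measured; the degree sum (summed over the three bands
per sample) separates the groups decisively — observed t far exceeds the
critical value, so the null hypothesis of equal means is rejected at 95%
confidence, and nearly all the metric's spread (98.7%) sits in the DILD
group. The other examples show single-sample graph construction
(`01_phantom_to_network.py`), the curve-family contrast
(`02_degree_fits.py`), and the connection-radius sweep
(`04_radius_sweep.py`).

A thin CLI wraps the same pipeline:

```
lungnet simulate --kind mixed_dild --seed 7 --out phantom.dcm
lungnet analyze --input phantom.dcm --origin 0,0 --rd 4 --delta 50 --out-dir out/
lungnet cohort --n-normal 30 --n-dild 30 --seed 1 --out-dir cohort_out/
```

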