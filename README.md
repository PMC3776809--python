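# seasurv

Seasonality testing for multi-site monthly disease-surveillance counts.

Given case-level records or monthly count tables from many reporting sites,
`seasurv` answers two questions: *does each individual site show a 12-month
seasonal cycle?* and *do the sites of a whole latitude sector fluctuate in
phase?* It bundles:

- **synthetic** — a Poisson count generator (quadratic trend × cosine
  seasonal cycle × linear reporting ramp-up) so the entire pipeline is
  testable without any external data;
- **prep** — minimum-case filtering, leading low-reporting-year trimming,
  quadratic ratio detrending, 12-month climatologies and normalization by
  the overall monthly mean;
- **arma** — seasonal vs non-seasonal ARMA model comparison (orders ≤ 2,
  seasonal period 12) classified into five tiers by the AIC evidence ratio
  exp(ΔAIC/2);
- **spectral** — periodogram (Fourier transform of the autocovariance) with
  Daniell smoothing, graded at 90/95/99% against a red-noise (AR1)
  background at the annual and semiannual frequencies;
- **montecarlo** — per-site test of the largest monthly-mean difference
  (max − min) against 10,000 random case-to-month reassignments, with
  add-one rank p-values (floor 1/10001 → 0.0001) and half-split checks;
- **hewitt** — circular maximum 6-consecutive-month rank-sum test, with the
  null distribution by Monte Carlo or exact enumeration (P(T ≥ 56) = 0.025,
  P(T ≥ 50) = 0.37, P(T ≥ 49) = 0.48, P(T = 57) = 12·6!·6!/12! ≈ 0.0130);
- **sector** — equal-weight aggregation of normalized climatologies over
  NH-extratropics / tropics / SH-extratropics (split at 23° latitude), a
  circular-shift Monte Carlo null that rotates each site's 12-month pattern
  independently, and half-split consistency reports.

## CLI

```sh
seasurv simulate --config config.yaml --outdir world/   # synthetic data
seasurv prepare  --counts world/counts.csv --sites world/sites.csv --outdir prep/
seasurv test-site --counts world/counts.csv --sites world/sites.csv --outdir out/
seasurv hewitt-table --method exact                     # null table p(T), T=40..57
seasurv sector --counts world/counts.csv --sites world/sites.csv --outdir out/
seasurv run-all --config config.yaml                    # everything
```

All inputs/outputs are UTF-8 comma-delimited text with headers: case tables
(`site,year,month`), long-format counts (`site,year,month,count`), site
metadata (`site,latitude`). Exit codes: 0 ok, 1 data error, 2 config error.
A minimal `run-all` config:

```yaml
seed: 1
outdir: out
synthetic:
  sectors:
    - {n_sites: 27, shared_peak: 2, peak_jitter: 1,
       size_range: [20, 100], span_range: [120, 240],
       amplitude_range: [0.2, 0.5], latitude_range: [30, 60]}
n_sims_site: 10000
n_sims_sector: 10000
```

Replace `synthetic:` with `counts:`/`sites:` paths to analyze real tables.

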