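# symte

Symbolic transfer-entropy analysis of monthly time-series.

`symte` implements an end-to-end pipeline for detecting Wiener–Granger
causal influence between monthly processes observed across geographic
units:

1. **Preprocessing** — continuous monthly series are seasonally adjusted and
   linearly detrended (joint OLS of trend + month-of-year profile), then
   symbolized to a binary up/down alphabet by residual sign; count series
   are symbolized against their median; several binary series can be
   aggregated by per-month mode. Dated event lists are binned to monthly
   occurrence indicators at national, in-state, or elsewhere scope.
2. **Information theory** — plug-in estimation of entropy, transfer entropy,
   and conditional (partial) transfer entropy on the binary series, using
   only lag-1 histories, plus an exact-pmf evaluator (`te_from_pmf`) usable
   as a closed-form oracle.
3. **Inference** — significance via a structure-preserving permutation test:
   the cause series is shuffled only within strata sharing the same
   present-time tuple of effect and conditioning symbols (20,000 surrogates
   by default, α = 0.05). Per-unit estimates are combined into one group
   statistic: the squared population-weighted sum of square-root transfer
   entropies over the sum of squared populations.
4. **Partitioning & spatial structure** — units are split into restrictive /
   permissive legal-environment clusters by exact 1-D two-means (threshold
   search, deterministic), and each unit gets a neighbor-interaction series:
   the per-month mode of its n geodesically nearest units' symbols.
5. **Studies** — three orchestrated analyses over group × cause tables with
   mutually conditioned causes, plus conditional-probability maps.
6. **Synthetic data** — generators with planted lag-1 couplings, confounder
   chains, bimodal legal environments, and population-proportional events,
   so the whole pipeline is testable offline. A packaged CSV of 87 US mass
   shootings (1999–2017, compiled from the Washington Post database) is
   included for the event-processing paths.

## Test

```bash
python -m pytest -q tests/
```

One acceptance test (`test_criterion_1_event_list_processing`) is
intentionally red: the stated two-states-without-events figure is not
derivable from the packaged 1999–2017 table (16 states have no event in
that window; the figure holds only for the source database's full
1966–2020 span).

## CLI

```bash
symte simulate --seed 1 --out fixtures/            # write synthetic CSV fixtures
symte cluster  --config cfg.yaml --out results/    # restrictive/permissive labels
symte study1   --config cfg.yaml --out results/    # national drivers
symte study2   --config cfg.yaml --out results/    # in-state vs elsewhere events
symte study3   --config cfg.yaml --out results/    # neighbor interaction sweep
symte probmap  --config cfg.yaml --out results/    # per-state conditional probabilities
```

The YAML config points at the input CSVs and fixes the study window,
exclusion list, number of surrogates `B`, `alpha`, seed, and the neighbor
counts for study 3 (see `symte.config.PipelineConfig` for all keys and
defaults). Outputs are CSV tables plus a JSON provenance sidecar with the
seed, `B`, and a config hash.

Real study inputs (state-level background checks, media counts, law
restrictiveness) can be obtained from the deposited dataset
(github.com/dynamicalsystemslaboratory/Causes-of-firearm-acquisition;
Mendeley doi 10.17632/pn7scdrzx2.1) and converted to the CSV layouts
described in `symte/io.py`; nothing is downloaded automatically.

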