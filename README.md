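# spikebench

A dual-backend spiking-network simulator and accuracy-benchmarking
package for current-based leaky integrate-and-fire (LIF) networks. It
pits a high-accuracy reference integrator (exact subthreshold solution,
optional off-grid spike times) against an emulation of fixed-point
neuromorphic hardware (s16.15 state arithmetic, 16-bit quantized weights
with a dynamic binary point, piecewise-constant-current integration,
16-slot delay ring buffers with a delay-extension stage), and quantifies
the differences with a full single-neuron and network-level accuracy
statistic suite plus a CPU-cycle cost model.

## Layout

| Module | Contents |
| --- | --- |
| `spikebench.lif_core` | exact propagator, separated exponential integration, off-grid threshold crossing, refractoriness, `run_single_neuron` with four backends |
| `spikebench.fixed_point` | s16.15 arithmetic, truncating 16-bit weight quantization, IEEE binary16/32/64 rounding, the compound-Poisson ring-buffer headroom bound, bit allocation |
| `spikebench.network_model` | population/projection specs, with-replacement connectivity (multapses), normal weight/delay draws, DC/Poisson drive, network scaling, seeded instantiation |
| `spikebench.engine` | vectorized grid propagation with 16-slot ring buffers, delay extension, 32-bit synapse-word packing, overflow counting, cost/slowdown model |
| `spikebench.accuracy_single` | cross-correlation histograms, membrane-trace Pearson correlation, accumulated lead/lag, warped spike-time RMSE |
| `spikebench.accuracy_network` | per-population rates / CV ISI / pairwise correlations, Freedman-Diaconis binning, Gaussian-KDE smoothing, KL divergence, seed-vs-method protocol |
| `spikebench.workbench` | CLI, TSV/JSON I/O (+shipped schemas), seeded Poisson input and fixtures, protocol orchestration |

## CLI

All commands are also subcommands of the umbrella `spikebench` command.

```sh
# single Poisson-driven neuron, any backend
simulate-neuron --backend precise --rate 8000 --duration-ms 16000 \
    --seed 1 --out runs/precise

# desk-scale 8-population network (10% of the nominal size)
simulate-network --backend exponential-fixed --drive dc --scale 0.1 \
    --duration-ms 10000 --seed 1234 --out runs/fixed

# accuracy reports
compare-single --precise runs/precise/spikes.tsv \
    --discrete runs/grid/spikes.tsv --h-ms 0.1 --out report.json
compare-network --ref runs/precise --test runs/fixed --out kl_report.json

# seed-vs-method KL comparison (three reference seeds)
seed-sensitivity --reference exact-grid --test-backend exponential-grid \
    --seed 1 --seed 2 --seed 3 --scale 0.1 --out seed_sensitivity.json

# CPU-cycle cost model
cost-report --h-ms 0.1 --synapses-per-neuron 10000
```

Network specs are JSON (`populations` / `projections` / per-population
`drive` sections; schema in
`src/spikebench/workbench/schemas/config.schema.json`); instantiated
synapses export to TSV. A built-in synthetic 8-population layered
network is used when no config is given.

## Notes

* Runs are bit-reproducible from `(config, seed)`; random substreams are
  derived per purpose as `default_rng([master_seed, crc32(kind),
  crc32(name)])`.
* The fixed-point backend chooses the weight binary point per population
  from the closed-form headroom bound (`fixed_point.ring_buffer_max`,
  5 SD overhead by default) and counts saturating ring-buffer additions
  instead of raising.
* Delays are grid-aligned, clipped below at the step, and limited to one
  extension stage plus the ring-buffer span (14.4 ms at a 0.1 ms step).
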