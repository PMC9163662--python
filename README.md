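# mea-nmj

Analysis toolkit for validating engineered neuromuscular co-cultures:
spike detection and network-burst analysis of motor-neuron networks on
multielectrode arrays (MEAs), culture maturity staging, and
quantification of myotube contractile activity before and after
α-bungarotoxin (BTX) blockade of the neuromuscular junction.

The package is aimed at in-vitro electrophysiology groups who record
iPSC-derived motor-neuron networks on 60-electrode MEAs (4 min at
10 kHz) and score NMJ function by counting myotube contractions from
video. It ships synthetic-data generators with known ground truth, so
every analysis stage can be validated by parameter recovery rather than
by eye.

## Methods at a glance

**Spike detection.** Each electrode trace is band-limited with a
4th-order Butterworth bandpass, 300–3,000 Hz (zero-phase by default),
and a spike timestamp is emitted wherever the filtered signal deviates
more than *k*·SD (default *k* = 7) from its mean, with a 1 ms dead time
collapsing each excursion to one event.

**Network bursts.** Spikes from all electrodes are binned into a
population firing-rate histogram (Δt = 50 ms). Bins with count
> mean + 5·SD of the histogram are candidate burst bins; candidates in
which fewer than 20% of the recording's active electrodes fire are
pruned; adjacent surviving bins merge into single bursts. Reported
measures are the network firing rate (total spikes / duration), the
burst fraction (spikes inside bursts / all spikes), and the number of
active electrodes.

**Maturity staging.** Cultures are staged by age: young (15–35 DIV),
middle-aged (42–56 DIV), old (63–70 DIV); other ages are unstaged.

**Contraction assay.** Myotubes are selected the day before the
experiment (more than 1 contraction/min over 5 min, with at least 1 in
each minute), contractions are counted in 10-min windows before and
after treatment, binned into 30-s intervals, and the response is
classified from the percent reduction 100·(1 − post/pre) —
`abolished` (post = 0), `reduced`, `unchanged`, or `increased`.

## Worked example

```python
from mea_nmj import BurstSpec, gen_spike_trains, summarize_network

epochs = [BurstSpec(s, 0.5, 40.0, 0.8) for s in (20, 60, 100, 140, 180)]
trains, truth = gen_spike_trains(60, 2.0, epochs, duration=240.0, seed=42)
trains.div = 49
summary, bursts = summarize_network(trains)
print(len(bursts), f"{summary.burst_fraction:.3f}", summary.stage)
```

prints

```
5 0.253 middle_aged
```

— all five planted synchronized epochs are recovered as network bursts,
25.3% of all spikes fall inside them, and a 49-DIV culture is staged
middle-aged. For the BTX worked numbers:

```python
from mea_nmj import percent_reduction, classify_response
print(f"{percent_reduction(124, 11):.2f}%", classify_response(124, 11))
```

```
91.13% reduced
```

— a myotube going from 124 contractions per 10 min before treatment to
11 after has lost over 91% of its contractile activity.

Longer narrative scripts live in `examples/` (spike detection, network
bursts, the contraction assay, and the full pipeline). A thin CLI wraps
the same API:

```
mea-nmj simulate trains --seed 1 --out sim/
mea-nmj analyze-network --spikes sim/spikes.csv --div 49 --out summary.json
mea-nmj run --seed 1 --out results/
```

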