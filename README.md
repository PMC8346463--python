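# damtrack

Processing pipeline for JSATS-style acoustic telemetry of juvenile salmonids
at hydropower dams: tag-code validation, false-positive filtering, TDOA-based
3-D localization, trajectory cleaning, dam passage-route assignment, and
GPS-referenced accuracy validation — with a synthetic-data simulator so every
stage is testable without a field deployment.

## The problem

Juvenile salmon migrating past dams are tracked with small acoustic
transmitters (31-bit coded pings at a nominal 4.2 s ping-rate interval, PRI)
and arrays of cabled hydrophones mounted on the dam piers, plus autonomous
single-hydrophone receivers strung across the river. Raw decodes are noisy:

* an 8-bit CRC protects the tag id, so random noise that decodes at all still
  *validates* once in 256 times (false positives);
* bit corruption of a real transmission can produce a different id with a
  valid CRC (a **mimic** tag-code);
* surface/bottom reflections duplicate decodes a few hundred ms after the
  direct arrival (**multipath**).

`damtrack` implements the standard filter cascade — per-hydrophone multipath
filter, cross-hydrophone message grouping, single-detection filter, PRI
(transmission-lattice) filter with detection-event building, mimic filter,
and a cross-array chronology check — then localizes each surviving
multi-hydrophone message by minimizing the hyperbolic TDOA objective

```
min_p  Σ_i ( Δt_i − (‖p − h_i‖ − ‖p − h_ref‖)/c )²
```

(damped Gauss–Newton from a coarse multi-start grid; `c` from water
temperature via the Marczak freshwater polynomial), cleans the resulting
track (45 m spatial / 10 min temporal / 2 m/s speed outlier rules), and
assigns each fish a passage route (main route / subroute / hole) from the
last 3-D position and, independently, from pier-averaged last detections,
reconciling the two. A simulated GPS-referenced USV survey (3 s PRI tag towed
at 0.28 m/s out to 150 m per bay) feeds median/RMS per-axis error tables in
10 m distance bins, the same shape used to report field accuracy.

## Worked example

```
damtrack all --config config.toml --out-dir out
```

with

```toml
[simulate]
seed = 1
n_fish = 2
duration = 600.0

[validate]
survey_bays = ["B02"]
```

prints (abridged):

```json
{
  "simulate": {"n_fish": 2, "n_decodes": 8911},
  "filter":   {"raw": 8911, "multipath": 7468, "messages": 366,
               "single_detection": 286, "pri_accepted": 286, "events": 2},
  "track":    {"n_track_points": 286},
  "route":    {"n_assignments": 2, "n_review": 0},
  "validate": {"medians": {"x": 0.019, "y": 0.0033, "z": 0.058},
               "rms":     {"x": 0.035, "y": 0.0060, "z": 0.109}, "n_bins": 15}
}
```

Reading the counts: 8,911 raw decodes (direct arrivals plus multipath echoes
and Poisson false positives) shrink to 7,468 after the multipath filter and
group into 366 candidate messages; 286 survive the single-detection and PRI
filters and form 2 detection events (one per fish); all 286 localize and
survive trajectory cleaning. Both fish get unflagged route assignments, e.g.

```
Tag_ID,Route,Subroute,Passage_Hole,Array_Name
7922,spillway,regular_spillway,B06,SYN
8306,powerhouse,turbine,T06,SYN
```

The validate stage tows a simulated GPS-referenced tag in front of spillbay
B02 and reports sub-decimeter median errors per axis at 10 µs timing noise,
with the depth (Z) error growing with distance from the dam — the
characteristic weak direction of a pier-mounted (near-planar) array.
`out/survey_accuracy_table.csv` holds the full 10 m-binned table (detection
efficiency, tracking efficiency, median and RMS X/Y/Z errors per bin).

Outputs use the study's CSV data-record schemas (hydrophone configuration,
tagged-fish list, event data, 3-D tracks, passage routes), so the pipeline
can equally be pointed at deposited field tables.

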