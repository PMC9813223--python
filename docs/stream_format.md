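# Raw-stream container format (`.lvs`), version 1

A single binary file holding the enabled pulse samples of an acquisition
plus the per-frame synchronization metadata.  All integers and floats are
little-endian.  Layout, in order:

| section      | size (bytes)      | contents                                   |
|--------------|-------------------|--------------------------------------------|
| magic        | 18                | ASCII `LISSAVOL-STREAM-1` + `\n` (0x0A)    |
| header       | variable          | one JSON object, UTF-8, terminated by `\n` |
| frame table  | 32 × `n_frames`   | records, see below                         |
| count table  | 8 × `n_frames`    | `<i8` enabled-sample count per frame       |
| pulse table  | 8 × `n_samples`   | `<i8` global pulse ordinal per sample      |
| value table  | 8 × `n_samples`   | `<f8` measured photons per sample          |

The JSON header has keys `format` (`"lissavol-stream"`), `version` (1),
`seed` (int), `n_frames`, `n_samples`, and `scan` (the full scan
configuration: `clocks`, `geometry`, `enable`, `tag_phase0`), serialized
with sorted keys.

Each frame-table record is 32 bytes, fields in order:

| field         | type  | meaning                                        |
|---------------|-------|------------------------------------------------|
| `frame_index` | `<i8` | global frame ordinal                           |
| `y_index`     | `<i8` | galvo line within the volume (`frame % n_y`)   |
| `t_start`     | `<f8` | opening time of the frame's first enable window, s |
| `delta_phi`   | `<f8` | TAG phase at `t_start`, rad, in [0, 2π)        |

Sample times are implicit: `t = pulse_ordinal / f_rep`.  Samples are
stored frame-contiguously in time order; frame `i`'s slice is delimited
by the cumulative sums of the count table.  Readers must validate the
magic, the version, and that every table is complete; writers always
produce the tables in the order above with no padding.
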