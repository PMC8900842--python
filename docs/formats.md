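# File formats

All formats are plain text, chosen for diffability in tests and archives.

## Curve file

One azimuthally integrated scattering curve I(q).

```
# trxss-curve
# <key> = <value>
# columns = q I sigma
<q> <I> <sigma>
...
```

* Header lines start with `#`.  `key = value` pairs carry metadata; the
  keys `temperature` (°C), `exposure` (s), `wavelength` (Å) and `t0` (s)
  are parsed as floats, everything else as strings.  The `columns` line is
  informational.
* Data rows are whitespace-delimited with 2 or 3 numeric columns:
  q [1/Å], intensity [counts/frame], optional standard uncertainty.
  q must be strictly increasing; violations are reported with the line
  number.
* Floats are written with `repr`, i.e. the shortest exact decimal form, so
  write → read → write is byte-identical.

## Scan directory

One pump-probe scan: alternating laser-off/on steps on a shared q grid.

```
scan/
  manifest.yaml
  qgrid.txt            # one q value per line, strictly increasing
  step_0000.txt        # frame-by-q intensity matrix, whitespace-delimited
  step_0001.txt
  ...
```

`manifest.yaml` keys:

* `format`: literally `trxss-scan`;
* `scheme`: the trigger scheme as `{frame_rate_hz, readout_s, step_s,
  dt1_s, tw1_s, dt2_s, tw2_s, secondary_rate_hz, train_s}`;
* `steps`: ordered records `{index, laser_state, frames_file, t0,
  exposure, frame_period}` — `t0` is the step start in seconds from scan
  start, `laser_state` is `"on"`/`"off"`, and frame timestamps are
  reconstructed as `frame_period * arange(n_frames)` (exposure-start
  convention);
* `metadata`: free-form key/value (seed, generator truth, pipeline config
  hash, ...).

Validation on load enforces the scan invariants (off/on alternation,
off first and last, one q grid and frame count throughout) and names the
offending step.  Matrix files are written with `%.17g`, which round-trips
doubles exactly.

## Difference-series directory

Written by `trxss reduce`; read by `trxss fit-temperature` / `trxss
kinetics`.

```
series/
  series.yaml          # type tag, n_repeats, source metadata
  qgrid.txt
  times.txt            # s from step start
  delta_I.txt          # frames x q matrix
  sem.txt              # optional, same shape
```

## Calibration file

A curve file holding the per-degree heating basis ΔI_heat(q) with
`reference_temperature` (°C) and `linearity_r2` in the header metadata.
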