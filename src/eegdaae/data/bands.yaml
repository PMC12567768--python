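# Canonical analysis band bank. `low`/`high` in Hz; null high means
# high-pass only ("All" band, everything above 1 Hz).
bands:
  - {name: Delta, low: 1.0, high: 4.0}
  - {name: Theta, low: 4.0, high: 8.0}
  - {name: Alpha, low: 8.0, high: 13.0}
  - {name: Beta, low: 13.0, high: 32.0}
  - {name: De2Be, low: 1.0, high: 32.0}
  - {name: Th2Be, low: 4.0, high: 32.0}
  - {name: Gamma, low: 32.0, high: 125.0}
  - {name: All, low: 1.0, high: null}
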