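# Versioned parameter presets for marimo-machines.
version: 1

photosynthesis:
  # Saturating light response r(PAR) = r_max * PAR / (PAR + K), calibrated
  # so strong sunlight yields 6.0 mL/day and moderate sunlight 2.6 mL/day
  # (inside the observed 1-3 mL/day band) for a ~60 mm alga ball.
  params:
    r_max_ml_per_day: 18.0
    half_saturation_umol_m2_s: 3000.0
    induction_lag_h: 4.0
    decline_timescale_days: 10.0
    damage_threshold_umol_m2_s: 3000.0
  irradiance:
    strong_sunlight: 1500.0
    moderate_sunlight: 500.0
    led_growth_light: 110.0

gates:
  # Declarative layouts: each column's ball is driven by one logical input
  # (input 0 = first bit, 1 = second bit); 'stack' names the float stack
  # that decides what the column does to a supply beam; each beam runs
  # through the listed columns in order to its sensor.  Gate output is the
  # OR of its sensors.
  nor:
    columns:
      - {name: A, input: 0, stack: block_when_up}
      - {name: B, input: 1, stack: block_when_up}
    beams:
      - {sensor: F1, path: [A, B]}
  and:
    columns:
      - {name: A, input: 0, stack: transmit_when_up}
      - {name: B, input: 1, stack: transmit_when_up}
    beams:
      - {sensor: F1, path: [A, B]}
  or:
    columns:
      - {name: A, input: 0, stack: transmit_when_up}
      - {name: B, input: 1, stack: transmit_when_up}
    beams:
      - {sensor: F1, path: [A]}
      - {sensor: F2, path: [B]}
  nand:
    columns:
      - {name: A, input: 0, stack: block_when_up}
      - {name: B, input: 1, stack: block_when_up}
    beams:
      - {sensor: F1, path: [A]}
      - {sensor: F2, path: [B]}
  xor:
    columns:
      - {name: A, input: 0, stack: transmit_when_up}
      - {name: B, input: 1, stack: block_when_up}
      - {name: C, input: 0, stack: block_when_up}
      - {name: D, input: 1, stack: transmit_when_up}
    beams:
      - {sensor: F1, path: [A, B]}
      - {sensor: F2, path: [D, C]}
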