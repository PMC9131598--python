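# Best-supported Aegean divergence scenario for the four regional demes.
# Backward in time: at t2 the central-western (CW) deme merges into the
# north-western (NW) deme; at t3 the NW and north-eastern (NE) demes merge
# into the northern (N) deme, which then takes the ancestral size Na.
# t0 is a recent effective-size change on CW (from Ne4 back to Na); its
# biological interpretation is unresolved but the parameter is retained so
# the scenario's parameter vector matches the published prior table.
name: scenario13
demes: [N, NE, NW, CW]
sizes:
  N: Ne1
  NE: Ne2
  NW: Ne3
  CW: Ne4
parameters:
  Ne1: {prior: log-uniform, low: 10, high: 1.0e+7}
  Ne2: {prior: log-uniform, low: 10, high: 1.0e+7}
  Ne3: {prior: log-uniform, low: 10, high: 1.0e+7}
  Ne4: {prior: log-uniform, low: 10, high: 1.0e+7}
  Na:  {prior: log-uniform, low: 10, high: 1.0e+5}
  t0:  {prior: log-uniform, low: 10, high: 1.0e+4}
  t2:  {prior: log-uniform, low: 10, high: 1.0e+6}
  t3:  {prior: log-uniform, low: 10, high: 2.0e+6}
events:
  - {type: size_change, time: t0, deme: CW, size: Na}
  - {type: merge, time: t2, source: CW, target: NW}
  - {type: merge, time: t3, source: NW, target: N}
  - {type: merge, time: t3, source: NE, target: N}
  - {type: size_change, time: t3, deme: N, size: Na}
constraints:
  - t0 < t2
  - t2 < t3
notes:
  t0_interpretation: unresolved
  generation_interval_years: 3
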