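# contrib — reconstructed influence networks

Influence-network transcriptions in this directory are **best-effort
reconstructions**: their topologies were inferred from drawings and
constraint descriptions rather than from explicit reaction lists, so they
are bundled here — outside the trusted fixture library in
`crnemu.netlib` — and are excluded from the acceptance checks.

Each file is an influence JSON loadable with
`crnemu.influence_from_json(json.load(open(path)))` and compilable with
`crnemu.compile_influence`.

- `qi.json` — quad-inhibition network: four nodes with two mutual-activation
  pairs (`y↔s`, `z↔r`) and an inhibition four-cycle (`y⊣z`, `z⊣s`, `s⊣r`,
  `r⊣y`). Under the species map `y,s ↦ y`, `r,z ↦ z` (triplets mapped
  directly) its compilation is a unit-rate homomorphism and
  net-stoichiomorphism onto the compiled MI network, hence an emulation for
  every MI rate assignment. The edge set satisfies every stated constraint
  and the emulation check, but other edge sets might too; treat it as one
  consistent reconstruction, not a canonical topology.
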