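# Built-in modifier parameter presets.
#
# Scavenger presets: published (FNSD, CHMX) pairs of the hyperbolic DMSO
# survival model, per radiation quality.  FNSD is the non-scavengeable
# fraction of lesions; CHMX (mol/L) halves the scavengeable component.
scavenger:
  cobalt60:       {fnsd: 0.52, chmx: 0.21}
  proton62MeV:    {fnsd: 0.52, chmx: 0.07}
  helium3.31MeV:  {fnsd: 0.75, chmx: 0.14}

# Default lesion-level oxygen hyperbola (low-LET starting point; the
# calibration routine refines m_lesion and k_o2 against the DSB-class OER
# endpoint and one intermediate-hypoxia yield).
oxygen:
  default: {m_lesion: 1.75, k_o2: 0.7, reference_o2: 21.0}

# Radiation-quality labels (LET in keV/um, for reporting only).
let_labels:
  cobalt60: 2.4
  proton62MeV: 1.051
  helium3.31MeV: 120.0
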