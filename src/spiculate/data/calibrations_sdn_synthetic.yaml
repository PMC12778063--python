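# Twelve-node calibration set, SDN arrangement (oldest siliceous spicule
# constrains the spiculate demosponge node).
#
# SYNTHETIC STAND-IN: the root, Eumetazoa and Heteroscleromorpha entries
# carry the documented bounds and tail masses; the remaining nine
# lower-bound entries use representative minimum ages chosen to be
# geologically plausible for the named clades, because the full
# node-by-node fossil list is not distributed with this package.  Offset p
# and scale c are restricted to the documented option sets {0.1, 0.5} and
# {0.5, 0.1}.  Replace the t_L values with your own fossil minima before
# any real dating analysis.
calibrations:
  - node: Porifera_root
    kind: uniform_soft
    t_L: 574.0
    t_U: 609.0
    p_L: 1.0e-300      # hard minimum
    p_U: 0.025         # soft maximum
  - node: Eumetazoa
    kind: uniform_soft
    t_L: 561.0
    t_U: 573.0
    p_L: 0.025         # soft minimum
    p_U: 1.0e-300      # hard maximum
  - node: Heteroscleromorpha       # oldest loose siliceous spicules (SDN)
    kind: cauchy_lower
    t_L: 515.0
    p: 0.5
    c: 0.5
    p_L: 1.0e-300
  - node: Silicea
    kind: cauchy_lower
    t_L: 535.0
    p: 0.1
    c: 0.5
    p_L: 1.0e-300
  - node: Demospongiae
    kind: cauchy_lower
    t_L: 515.0
    p: 0.1
    c: 0.5
    p_L: 1.0e-300
  - node: Hexactinellida
    kind: cauchy_lower
    t_L: 535.0
    p: 0.5
    c: 0.5
    p_L: 1.0e-300
  - node: Calcarea_Homoscleromorpha
    kind: cauchy_lower
    t_L: 535.0
    p: 0.1
    c: 0.5
    p_L: 1.0e-300
  - node: Calcarea
    kind: cauchy_lower
    t_L: 509.0
    p: 0.5
    c: 0.1
    p_L: 1.0e-300
  - node: Homoscleromorpha
    kind: cauchy_lower
    t_L: 335.0
    p: 0.5
    c: 0.5
    p_L: 1.0e-300
  - node: Keratosa
    kind: cauchy_lower
    t_L: 307.0
    p: 0.5
    c: 0.1
    p_L: 1.0e-300
  - node: Tetractinellida
    kind: cauchy_lower
    t_L: 166.1
    p: 0.1
    c: 0.1
    p_L: 1.0e-300
  - node: Haplosclerida
    kind: cauchy_lower
    t_L: 145.0
    p: 0.5
    c: 0.1
    p_L: 1.0e-300
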