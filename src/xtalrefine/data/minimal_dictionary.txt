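# xtalrefine minimal restraint dictionary
#
# Format (whitespace-separated, '#' comments):
#   residue <NAME>
#     atoms  <name> [<name> ...]
#     bond   <a1> <a2> <ideal A> <sigma A>
#     angle  <a1> <a2> <a3> <ideal deg> <sigma deg>
#     chir   <centre> <n1> <n2> <n3> <ideal signed volume A^3> <sigma A^3>
#     plane  <a1> <a2> ... <sigma A>
#     torsion <name> <a1> <a2> <a3> <a4> <ideal deg> <period> <sigma deg> <restrain|free>
#   link <NAME>            (atoms of the following residue carry a '+' prefix)
#     ... same records ...
#   end
#
# Ideal values are fixture conventions for toy systems (Engh & Huber-like
# magnitudes); sigmas are plain-text declared defaults.

residue GLY
  atoms N CA C O
  bond N CA 1.451 0.016
  bond CA C 1.516 0.018
  bond C O 1.231 0.012
  angle N CA C 112.5 1.5
  angle CA C O 120.8 1.5
end

residue ALA
  atoms N CA C O CB
  bond N CA 1.458 0.014
  bond CA C 1.525 0.016
  bond C O 1.231 0.012
  bond CA CB 1.521 0.018
  angle N CA C 111.0 1.5
  angle CA C O 120.8 1.5
  angle N CA CB 110.4 1.5
  angle CB CA C 110.5 1.5
  chir CA N C CB 2.484996 0.2
end

residue SER
  atoms N CA C O CB OG
  bond N CA 1.458 0.014
  bond CA C 1.525 0.016
  bond C O 1.231 0.012
  bond CA CB 1.521 0.018
  bond CB OG 1.417 0.016
  angle N CA C 111.0 1.5
  angle CA C O 120.8 1.5
  angle N CA CB 110.4 1.5
  angle CB CA C 110.5 1.5
  angle CA CB OG 111.1 2.0
  chir CA N C CB 2.484996 0.2
  torsion chi1 N CA CB OG 180.0 3 15.0 restrain
end

residue CYS
  atoms N CA C O CB SG
  bond N CA 1.458 0.014
  bond CA C 1.525 0.016
  bond C O 1.231 0.012
  bond CA CB 1.521 0.018
  bond CB SG 1.808 0.020
  angle N CA C 111.0 1.5
  angle CA C O 120.8 1.5
  angle N CA CB 110.4 1.5
  angle CB CA C 110.5 1.5
  angle CA CB SG 114.4 2.0
  chir CA N C CB 2.484996 0.2
  torsion chi1 N CA CB SG 180.0 3 15.0 restrain
end

residue HOH
  atoms O
end

# toy ligand: a three-atom ether fragment
residue LIG
  atoms C1 O1 C2
  bond C1 O1 1.430 0.020
  bond C1 C2 1.520 0.020
  angle O1 C1 C2 109.5 2.0
end

link PEPTIDE
  bond C +N 1.329 0.014
  angle CA C +N 116.2 1.5
  angle O C +N 123.0 1.5
  angle C +N +CA 121.7 1.8
  torsion omega CA C +N +CA 180.0 1 5.0 restrain
  plane CA C O +N 0.02
end
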