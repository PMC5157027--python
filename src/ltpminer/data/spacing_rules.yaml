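# Inter-cysteine spacing rules for the eight nsLTP subfamilies found in
# Gossypium (Boutrot-style typing by the gaps of the eight-cysteine motif
# C-Xn-C-Xn-CC-CXC-Xn-C-Xn-C).  Gap names: head = residues before Cys1,
# g12 = residues between Cys1 and Cys2, g23 between Cys2 and Cys3,
# g45 between the CC block (Cys4) and Cys5, g67 between the CXC block
# (Cys6) and Cys7, g78 between Cys7 and Cys8, tail = residues after Cys8.
# Each list is the finite set of observed gap lengths for that subfamily.
version: 1
types:
  I:
    members: 63
    head: [2, 3, 4, 5, 7, 9]
    g12: [9]
    g23: [13, 14, 15, 16]
    g45: [19, 20]
    g67: [19, 21, 22, 23, 24]
    g78: [13, 14, 15]
    tail: [2, 3, 4, 5, 7, 8, 10, 19, 20, 21, 23, 25]
  II:
    members: 44
    head: [2, 5, 6, 8, 9, 10, 11, 13, 14]
    g12: [7, 8]
    g23: [12, 13, 14]
    g45: [8]
    g67: [23]
    g78: [6, 7, 9]
    tail: [0]
  III:
    members: 4
    head: [2, 8]
    g12: [9]
    g23: [16]
    g45: [9]
    g67: [12]
    g78: [6]
    tail: [1, 2, 4]
  IV:
    members: 22
    head: [3, 6]
    g12: [9]
    g23: [15, 17]
    g45: [9]
    g67: [22, 24]
    g78: [7, 9]
    tail: [0, 2, 7, 11, 12]
  V:
    members: 32
    head: [3, 7]
    g12: [14]
    g23: [14]
    g45: [11, 12]
    g67: [24]
    g78: [10]
    tail: [3, 4, 6, 7, 12, 14, 17, 19, 23]
  VI:
    members: 7
    head: [1, 5, 6, 9]
    g12: [10]
    g23: [12, 16]
    g45: [9]
    g67: [22]
    g78: [9]
    tail: [6, 8, 9, 10, 11]
  VIII:
    members: 11
    head: [3, 4, 8]
    g12: [6]
    g23: [14]
    g45: [12]
    g67: [25, 27]
    g78: [8]
    tail: [6, 13, 16, 20, 21, 24, 37]
  IX:
    members: 3
    head: [2]
    g12: [13]
    g23: [15]
    g45: [9]
    g67: [22]
    g78: [6]
    tail: [4]
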