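pretag:
  description: 'Pre-tagging cassette: selection marker (nat stand-in) flanked by the same terminal epitope
    linkers as every final tag, enabling universal cassette exchange.'
  marker: TATGCTGTGAATGATCAGCAACGTGCGAGCTCTGTGAAAGATTGATGTTACCTTGCGCTATCCCTAGAGGTTGCGTCTGTTAATAAACCATCCATCATGCGTTCTCGTGCGACGGCCTCTAGCGCTGGAGTTCTTTCATCTGTGCATCCAGCGCTTAACTCTGATGGCAAGGTCGGAACACCTTGCCCCTTGCACTGTCCTACGCCACCCTCATCGCATTTCTGAGAGTGATCTGCGGGATCTGACTTTCATTTCGCCAGACTCGGCTCCTGGTGTCAAGCGGGTGCTGCTGCAAGAGGCGCTGGAGGGAGCCACCGGAGGTGATACAGTTAGCACGGAACACAAGAAATTTCACTCTCCTGATGTTACCCATGCAGGTCAGGTGCCACTGCAATTTGAGCTTTACAGCAGTTAATCTTCTTCCTAGTGCGTTTCGCGGCGTCCTAGCATTTAAGTCCGGCGTTGCATCGCTTCGGAGACCGATGCTGAGCGAGAATCGGGCGTACCAACCCCCGCGATACGATAGGTAAACGCAAAGCCACATCCCCCTGTACCGGGCCACTCGTACCCTAA
sgfp_tag:
  description: 'C-terminal multi-epitope fluorescent tag: 2xTY1 linker, superfolder-GFP, V5, TEV protease
    site, biotin-ligase peptide, FRT-flanked selection operon, 3xFLAG. Synthetic stand-in sequences with
    the structural properties of the published cassette.'
  segments:
  - - linker-epitope
    - GACGCTCCGAGTTCCACTCCTAACATTAAAGCTGCTCCCGGTAGCTGCTCTAATAAAGCT
  - - fluorophore
    - ACTGAATGCCGTGCGGCGTACTACCCTACCTCCCGATACCGAATCCTATGCCGGCCAGGAGTTCCAGCGGTGCTGAAAGCGTATGAAACTGAGTGGCGATCAAACTGTAGCTTCCTAACGGGGCAACCTCCAGGCTCTCCATTAGCAAGAAAATGTAGGAGTTGTGGTCTACTTGACGGCGCTCAGTACAAATCCCCGTCCGCCTGGGATGAGCGGGCCTTATCACGGGACGATCTTTTGCGAAGGTATCCCGCCTCGGAATGTCGTCTTATAACAGGAGAGCAGGAGTGTGAACTCTTCACCTACCTATTACAAGCACAGATCCACTGTAGGCGATACGAGTTGGAGAGACATGGGCCGCCATCATGGCCTGACCATTCCTATTCTCTTTTATGCCATTTTGCCAAGGAGCAGGGCGCGACATTGGTGGAAGTGATTGCTTGTATAAGTTTGGACACTCTGCAGAATCAGCAAGTTATAGTCGGTGTGTGGGGGAGGGTGTATTGGTCTATCGCCGTAGACATAAGGGTGGTCAAACCCAGACCAAGATCGATTACCCACGCCTCGATCAGCTGTAGTCGTTGGTCTTTATGGAGGCGCTCAGGGGACGACACTCCGCGGGGGCCGCGTACGGGGTCTGAATCGTGCCACGGGCCTCTATGTACACAAGCATTTCGTCACACTGCTCCTTCGGGCGTCGCCTCACTAGGCCTA
  - - epitope
    - CAAGGATCCCTCGTTGGTGCCTTACAGCCCCCAAGCTCAGAT
  - - protease-site
    - TTACGGTATCTGGGGTCGTTC
  - - blrp
    - GACTACGTAACAGGTCTTTCCGCCAGGCTCTCGTCCGGGTGTGAT
  - - stop-free-spacer
    - A
  - - frt
    - GAAGTTCCTATTCTCTAGAAAGTATAGGAACTTC
  - - selection-marker
    - TGCTTAGAGTGAACCCAGAGATCGGAGCAACAAATGATCTGTAACTTCGCCTCAATTGGTGTATTAGCTCAAGCAGAGCCGCTATTCTACCGGACTTGTTGAGCATACTATGAGACGCATGTTCGTCGAGGGCCCGTTCGTACATGACTACGACACCTGCGGATTGGCGAGCCTCAGTCAACCCGCGCGCCCATACTGATTAGCTAGGATGACCAGTGCAGATTTGGATCAATACAATGTGCAATGCTAAGAACAAATGACAACTCACTCAGTTCCCAAACAACCGGGCGGCATTTATCAGCGCTCCCCCTCCGGGTAACAAAACGGAGATGCTCCTCTCGTTTCTAGACAACGATGATGATTGCAATTGGCATTGATTGGCGATTCGTATTCTGACACGATACTGTCTTTTCTCACACGCCTATTACGTTTGGAAATGAGCCAGACCTGGAATAAACCAAGACTACAAGTTGGCTACAGTGGCCGAAGTTTCCCGACGGACACTTGAGCTTCGCCTCCGATGGGGTGTCGCGCTGAAACACTGCGATACGAGAAGCTATACTCACCCAGTGGTCAGTACCAACGGTATAGTGTTAACCGCCAGAACCCAGACAGCATCAAAACACTCGACGGAGATCAACCCTCCGTTTGGGTTCCACTTAGTTCGCGTCCCATATATCTTAATTTCGGCGACAGATTGGTACGCCTTTTCGTAGTTCAATAGATGGTCCAACCTTTACGTAGGAGTCAAAGGTCGTCCGCCCTTGATTGCTGGCACTGATGAGGAAGAGCGGGGCAAGGCGGGTGGGCTATAGAACCACTAAGCGGCCTATACTCTTAGTTAGCGTTCCCCCAAAGTTTCAACACCGGTTATCCGACGATGTTTGCCCCCTTGTTGTACTCTATTAAGAGTTACTTAGTCTATGAGGCGTAGTTCATGTTGTATCCTGATAGGGGTGCGCTCTGACGCCAAGCGCTTGAACTTATTCAGACCTCATCTGTTATCACTCCGAAGGCCGGTGGTCAAGGGATACAGCGTGCGTCAGCCACCCATTGTACACACGTAGGACTAAGTTAATTTGTTGCGCGGATACTCAATTATACGTAGTCCCGTCCGAATGTCCCCGTGAAACACCGCTACCATTAGCGCCAGTGCATGACTCGGTCTCTTTGATAACTCGCAGACAATCTGTGTGCCCGCTAGTGTGGTACGGCCGCGACCACTGAGCCATCCACCCTAAGTCAGACTAAGGATGAATCTCACGACCGTCACACACTCCAGTGGGTACGCGGTTTCCGATG
  - - frt
    - GAAGTTCCTATTCTCTAGAAAGTATAGGAACTTC
  - - stop-free-spacer
    - AGGC
  - - epitope
    - GCGGGTTGCGCCAGGTTCCCACTTCCTCTCACAGGCACTGATCTACTCATCCGAAGCCCCAGTTGG
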