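# Topology alias bindings for the six pruned duck taxa.
# Values are branch-length-free newick shapes; they are rerooted on the
# outgroup and re-canonicalised on load, so the written rooting and child
# order do not matter.
#   t1 / tree-1: steamer ducks outside; (Baikal, Shoveler) with Pekin
#   t2 / tree-2: steamer ducks grouped with Pekin (introgression topology)
#   t3 / tree-3: steamer ducks grouped with (Baikal, Shoveler)
outgroup: Muscovy
aliases:
  t1: "(Muscovy,((Steamer1,Steamer2),((Baikal,Shoveler),Pekin)))"
  t2: "((Muscovy,(Baikal,Shoveler)),((Steamer1,Steamer2),Pekin))"
  t3: "(Muscovy,(((Steamer1,Steamer2),(Baikal,Shoveler)),Pekin))"
  tree-1: "(Muscovy,((Steamer1,Steamer2),((Baikal,Shoveler),Pekin)))"
  tree-2: "((Muscovy,(Baikal,Shoveler)),((Steamer1,Steamer2),Pekin))"
  tree-3: "(Muscovy,(((Steamer1,Steamer2),(Baikal,Shoveler)),Pekin))"
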