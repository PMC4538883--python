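{
 "format": "treebase-net-v1",
 "name": "fig6i",
 "comment": "Cyclic (u -> v -> w -> u): technically not a binary phylogenetic network; validation reports the cycle.",
 "vertices": [
  {
   "id": "rho"
  },
  {
   "id": "u"
  },
  {
   "id": "v"
  },
  {
   "id": "w"
  },
  {
   "id": "x",
   "label": "x"
  },
  {
   "id": "y",
   "label": "y"
  }
 ],
 "arcs": [
  {
   "id": "e00",
   "source": "rho",
   "target": "u"
  },
  {
   "id": "e01",
   "source": "u",
   "target": "v"
  },
  {
   "id": "e02",
   "source": "v",
   "target": "w"
  },
  {
   "id": "e03",
   "source": "v",
   "target": "x"
  },
  {
   "id": "e04",
   "source": "w",
   "target": "u"
  },
  {
   "id": "e05",
   "source": "w",
   "target": "y"
  }
 ]
}
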