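{
 "format": "treebase-net-v1",
 "name": "fig1",
 "comment": "Three-leaf tree-based network that can be based on all three rooted triples; two reticulations (v, w). Internal ids are the transcriber's choice.",
 "vertices": [
  {
   "id": "a",
   "label": "a"
  },
  {
   "id": "b",
   "label": "b"
  },
  {
   "id": "c",
   "label": "c"
  },
  {
   "id": "m"
  },
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
   "id": "z"
  }
 ],
 "arcs": [
  {
   "id": "e00",
   "source": "rho",
   "target": "m"
  },
  {
   "id": "e01",
   "source": "rho",
   "target": "v"
  },
  {
   "id": "e02",
   "source": "m",
   "target": "u"
  },
  {
   "id": "e03",
   "source": "m",
   "target": "w"
  },
  {
   "id": "e04",
   "source": "u",
   "target": "a"
  },
  {
   "id": "e05",
   "source": "u",
   "target": "v"
  },
  {
   "id": "e06",
   "source": "v",
   "target": "z"
  },
  {
   "id": "e07",
   "source": "z",
   "target": "w"
  },
  {
   "id": "e08",
   "source": "z",
   "target": "c"
  },
  {
   "id": "e09",
   "source": "w",
   "target": "b"
  }
 ]
}
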