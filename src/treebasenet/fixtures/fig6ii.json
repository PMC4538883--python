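{
 "format": "treebase-net-v1",
 "name": "fig6ii",
 "comment": "Acyclic and tree-based but with no strong temporal ordering relative to any support tree: the two crossing linking arcs force t(x1) < t(x1) in either support tree.",
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
   "id": "rho"
  },
  {
   "id": "x1"
  },
  {
   "id": "x2"
  },
  {
   "id": "y1"
  },
  {
   "id": "y2"
  }
 ],
 "arcs": [
  {
   "id": "e00",
   "source": "rho",
   "target": "x1"
  },
  {
   "id": "e01",
   "source": "rho",
   "target": "y1"
  },
  {
   "id": "e02",
   "source": "x1",
   "target": "x2"
  },
  {
   "id": "e03",
   "source": "x1",
   "target": "y2"
  },
  {
   "id": "e04",
   "source": "y1",
   "target": "y2"
  },
  {
   "id": "e05",
   "source": "y1",
   "target": "x2"
  },
  {
   "id": "e06",
   "source": "x2",
   "target": "a"
  },
  {
   "id": "e07",
   "source": "y2",
   "target": "b"
  }
 ]
}
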