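{
 "format": "treebase-net-v1",
 "name": "fig3",
 "comment": "Not tree-based although the antichain-to-leaf property holds: propagating t-labels from S1 forces both out-arcs of v to f, and the next (C2)' application would assign one of them a second label t.",
 "vertices": [
  {
   "id": "m"
  },
  {
   "id": "p1"
  },
  {
   "id": "p2"
  },
  {
   "id": "q1"
  },
  {
   "id": "r1"
  },
  {
   "id": "r2"
  },
  {
   "id": "rho"
  },
  {
   "id": "s1"
  },
  {
   "id": "s2"
  },
  {
   "id": "v"
  },
  {
   "id": "w1"
  },
  {
   "id": "w2"
  },
  {
   "id": "x",
   "label": "x"
  },
  {
   "id": "y",
   "label": "y"
  },
  {
   "id": "z",
   "label": "z"
  }
 ],
 "arcs": [
  {
   "id": "e00",
   "source": "rho",
   "target": "s1"
  },
  {
   "id": "e01",
   "source": "rho",
   "target": "s2"
  },
  {
   "id": "e02",
   "source": "s1",
   "target": "p1"
  },
  {
   "id": "e03",
   "source": "s1",
   "target": "m"
  },
  {
   "id": "e04",
   "source": "s2",
   "target": "p1"
  },
  {
   "id": "e05",
   "source": "s2",
   "target": "w1"
  },
  {
   "id": "e06",
   "source": "m",
   "target": "q1"
  },
  {
   "id": "e07",
   "source": "m",
   "target": "r1"
  },
  {
   "id": "e08",
   "source": "p1",
   "target": "q1"
  },
  {
   "id": "e09",
   "source": "q1",
   "target": "v"
  },
  {
   "id": "e10",
   "source": "v",
   "target": "r1"
  },
  {
   "id": "e11",
   "source": "v",
   "target": "r2"
  },
  {
   "id": "e12",
   "source": "r1",
   "target": "w2"
  },
  {
   "id": "e13",
   "source": "w2",
   "target": "p2"
  },
  {
   "id": "e14",
   "source": "w2",
   "target": "z"
  },
  {
   "id": "e15",
   "source": "w1",
   "target": "p2"
  },
  {
   "id": "e16",
   "source": "w1",
   "target": "x"
  },
  {
   "id": "e17",
   "source": "p2",
   "target": "r2"
  },
  {
   "id": "e18",
   "source": "r2",
   "target": "y"
  }
 ]
}
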