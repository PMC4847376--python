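<Program>
  <ExecParams>
    <SimTime>10</SimTime>
    <Seed>1</Seed>
  </ExecParams>
  <FunHandleName>lotka_volterra</FunHandleName>
  <Rule>
    <Name>Prey</Name>
    <InitPop>900</InitPop>
    <Rate>1</Rate>
    <Prod>
      <Products>Prey,Prey</Products>
      <Prob>0.5</Prob>
    </Prod>
    <Prod>
      <Products></Products>
      <Prob>ow</Prob>
    </Prod>
  </Rule>
  <Rule>
    <Name>Predator</Name>
    <InitPop>900</InitPop>
    <Rate>1</Rate>
    <Prod>
      <Products>Predator,Predator</Products>
      <Prob>0.5</Prob>
    </Prod>
    <Prod>
      <Products></Products>
      <Prob>ow</Prob>
    </Prod>
  </Rule>
</Program>
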