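<Program>
  <ExecParams>
    <SimTime>10</SimTime>
    <Seed>1</Seed>
  </ExecParams>
  <FunHandleName></FunHandleName>
  <Rule>
    <Name>SC</Name>
    <InitPop>50</InitPop>
    <Rate>0.1</Rate>
    <Prod>
      <Products>SC,SC</Products>
      <Prob>0.5</Prob>
    </Prod>
    <Prod>
      <Products>Diff,Diff</Products>
      <Prob>ow</Prob>
    </Prod>
    <InternalState>
      <Name>MS</Name>
      <InitVal>30</InitVal>
      <FuncName>ms_step</FuncName>
      <DupNum>5</DupNum>
    </InternalState>
  </Rule>
  <Rule>
    <Name>Diff</Name>
    <InitPop>0</InitPop>
    <Rate>1</Rate>
    <Prod>
      <Products>Diff,Diff</Products>
      <Prob>0.49</Prob>
    </Prod>
    <Prod>
      <Products></Products>
      <Prob>ow</Prob>
    </Prod>
    <InternalState>
      <Name>MS</Name>
      <InitVal>30</InitVal>
      <FuncName>ms_step</FuncName>
      <DupNum>5</DupNum>
    </InternalState>
    <InternalState>
      <Name>Gen</Name>
      <InitVal>1</InitVal>
      <FuncName>gen_increment</FuncName>
      <DupNum>1</DupNum>
    </InternalState>
  </Rule>
</Program>
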