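<Program>
  <ExecParams>
    <SimTime>100</SimTime>
    <Seed>1</Seed>
  </ExecParams>
  <FunHandleName></FunHandleName>
  <Rule>
    <Name>SCASym</Name>
    <InitPop>1</InitPop>
    <Rate>0.1</Rate>
    <Prod>
      <Products>SCASym,SCSym</Products>
      <Prob>1</Prob>
    </Prod>
  </Rule>
  <Rule>
    <Name>SCSym</Name>
    <InitPop>1</InitPop>
    <Rate>0.1</Rate>
    <Prod>
      <Products>SCSym,SCSym</Products>
      <Prob>1</Prob>
    </Prod>
    <InternalState>
      <Name>CounterStoch</Name>
      <InitVal>0</InitVal>
      <FuncName>stochastic_counter</FuncName>
      <DupNum>1</DupNum>
    </InternalState>
    <ConditionalTransition>
      <Condition>CounterStoch &gt; 5</Condition>
      <Transition>Diff</Transition>
    </ConditionalTransition>
  </Rule>
  <Rule>
    <Name>Diff</Name>
    <InitPop>0</InitPop>
    <Rate>1</Rate>
    <Prod>
      <Products>Diff,Diff</Products>
      <Prob>0.5</Prob>
    </Prod>
    <Prod>
      <Products></Products>
      <Prob>ow</Prob>
    </Prod>
    <InternalState>
      <Name>CounterStoch</Name>
      <InitVal>0</InitVal>
      <FuncName>stochastic_counter</FuncName>
      <DupNum>1</DupNum>
    </InternalState>
    <ConditionalTransition>
      <Condition>CounterStoch &gt; 10</Condition>
      <Transition>{0}</Transition>
    </ConditionalTransition>
  </Rule>
</Program>
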